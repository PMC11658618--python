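"""Core domain types shared across the pipeline.

Coordinates are 1-based inclusive throughout (VCF convention); BED exports
convert to 0-based half-open at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

BASES = ("A", "C", "G", "T")


class PamTraceError(Exception):
    """Base class for pipeline errors."""


class ConfigurationError(PamTraceError):
    """Invalid simulation or pipeline configuration."""


class ReferenceMismatchError(PamTraceError):
    """A variant's REF allele disagrees with the reference sequence."""


@dataclass(frozen=True, order=True)
class Variant:
    """A single base substitution relative to the reference."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"ref/alt must be single bases, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.contig}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")

    @property
    def id(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref}>{self.alt}"

    @classmethod
    def from_id(cls, vid: str) -> "Variant":
        contig, pos, change = vid.rsplit(":", 2)
        ref, alt = change.split(">")
        return cls(contig, int(pos), ref, alt)


@dataclass(frozen=True)
class VariantCall:
    """One observation of a variant in one sample."""

    variant: Variant
    sample: str
    vaf: float
    depth: int
    mapping_quality: float = 60.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"VAF out of [0,1]: {self.vaf}")
        if self.depth < 0:
            raise ValueError(f"negative depth: {self.depth}")


class Strand(str, Enum):
    PLUS = "+"
    MINUS = "-"


class GenomicContext(str, Enum):
    CODING = "coding"
    INTRON_OR_NEAR_CODING = "intron_or_near_coding"
    INTERGENIC = "intergenic"


@dataclass
class PamEvent:
    """A somatic SBS together with one novel NGG register it creates.

    ``pam_register`` is the 1-based start of the 3-base motif in plus-strand
    coordinates; for minus-strand events the plus-strand sequence at the
    register reads CCN. ``protospacer`` is the 20-mer immediately 5' of the
    PAM on the PAM strand (reverse-complemented for minus-strand events).
    """

    variant: Variant
    strand: Strand
    pam_register: int
    protospacer: str | None = None
    gc_fraction: float | None = None
    gc_optimal: bool | None = None
    designable: bool = True
    context: GenomicContext | None = None

    @property
    def id(self) -> str:
        return self.variant.id


@dataclass(frozen=True)
class CopyNumberSegment:
    """Integer total copy number over a 1-based inclusive interval."""

    contig: str
    start: int
    end: int
    total_cn: int
    sample: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start > end: {self.start} > {self.end}")
        if self.total_cn < 0:
            raise ValueError(f"negative copy number: {self.total_cn}")

    def covers(self, contig: str, pos: int) -> bool:
        return self.contig == contig and self.start <= pos <= self.end


class ZygosityState(str, Enum):
    LOH = "LOH"
    HET = "HET"
    UNINFORMATIVE = "UNINFORMATIVE"


class RegionLabel(str, Enum):
    TRUNCAL_LOH = "TRUNCAL_LOH"
    PRIVATE_LOH = "PRIVATE_LOH"
    RETAINED_HET = "RETAINED_HET"
    UNINFORMATIVE = "UNINFORMATIVE"


@dataclass
class RegionZygosityStatus:
    """Per-region zygosity call across a case's tumor samples."""

    region: str
    sample_states: dict[str, ZygosityState]
    label: RegionLabel


class SampleRole(str, Enum):
    NORMAL = "normal"
    PRIMARY = "primary"
    METASTASIS = "metastasis"


@dataclass(frozen=True)
class GeneModel:
    """A gene body interval with coding subintervals (1-based inclusive)."""

    contig: str
    start: int
    end: int
    name: str = ""
    coding: tuple[tuple[int, int], ...] = field(default_factory=tuple)


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")
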