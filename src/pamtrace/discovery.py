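"""Discovery of somatic SBS that create novel SpCas9 NGG PAM registers.

A somatic single base substitution creates a novel PAM when the mutant
sequence matches NGG at some 3-base register/strand where the germline
sequence does not. Because N matches any base, only a new G (plus strand)
or new C (minus strand, whose plus-strand image is CCN) can create a
register, so at most two events exist per SBS and the strand is forced by
the alt base. Registers are compared exactly (register-based novelty), so
extending a germline GGG run by one G correctly yields one new register.
"""

from __future__ import annotations

import logging

from intervaltree import IntervalTree

from .model import (
    GeneModel,
    GenomicContext,
    PamEvent,
    PamTraceError,
    ReferenceMismatchError,
    Strand,
    Variant,
    VariantCall,
    revcomp,
)

log = logging.getLogger(__name__)

PROTOSPACER_LEN = 20
GC_OPTIMAL_RANGE = (0.40, 0.80)  # inclusive bounds for efficient sgRNA
DEFAULT_NEAR_WINDOW = 2000


def somatic_subtract(tumor: list[VariantCall], normal: list[VariantCall],
                     min_mq: float = 20.0, min_depth: int = 10,
                     min_af: float = 0.05) -> list[Variant]:
    """Somatic SBS: tumor calls passing quality filters minus normal variants.

    Tumor calls must pass mapping quality >= ``min_mq``, depth >=
    ``min_depth``, and allele fraction >= ``min_af``. A variant is removed
    when the same (contig, pos, ref, alt) shows allele support at or above
    ``min_af`` in the normal sample (zero-support capture records in the
    normal do not veto). Non-SBS records are dropped with a logged count.
    """
    tumor_names = {c.sample for c in tumor}
    normal_names = {c.sample for c in normal}
    if tumor_names and tumor_names == normal_names:
        raise PamTraceError(f"tumor and normal are the same sample: {sorted(tumor_names)}")
    normal_keys = {c.variant for c in normal if c.vaf >= min_af}
    out: list[Variant] = []
    seen: set[Variant] = set()
    n_failed = 0
    for call in tumor:
        v = call.variant
        if call.mapping_quality < min_mq or call.depth < min_depth or call.vaf < min_af:
            n_failed += 1
            continue
        if v in normal_keys or v in seen:
            continue
        seen.add(v)
        out.append(v)
    if n_failed:
        log.info("somatic_subtract: %d tumor calls failed MQ/depth/AF filters", n_failed)
    return sorted(out)


def _register_matches_ngg(seq: str) -> bool:
    return seq[1] == "G" and seq[2] == "G"  # N matches anything


def _register_matches_ccn(seq: str) -> bool:
    return seq[0] == "C" and seq[1] == "C"  # minus-strand NGG seen on plus strand


def scan_novel_pams(reference: dict[str, str], variant: Variant) -> list[PamEvent]:
    """Enumerate novel NGG registers created by one SBS.

    Checks every 3-base register overlapping the mutated position on both
    strands; a register is novel iff the mutant matches NGG (plus) or CCN
    (minus, plus-strand image) and the germline does not at the same
    register and strand. Registers running past contig ends are skipped.
    Protospacer and GC content are filled in for each event.
    """
    seq = reference.get(variant.contig)
    if seq is None:
        raise PamTraceError(f"unknown contig {variant.contig!r}")
    pos = variant.pos
    if not 1 <= pos <= len(seq):
        raise PamTraceError(f"position {pos} outside contig {variant.contig}")
    if seq[pos - 1] != variant.ref:
        raise ReferenceMismatchError(
            f"REF mismatch at {variant.contig}:{pos}: variant says {variant.ref}, "
            f"reference has {seq[pos - 1]}")
    events: list[PamEvent] = []
    for start in (pos - 2, pos - 1, pos):  # register starts covering pos
        if start < 1 or start + 2 > len(seq):
            continue
        germ = seq[start - 1:start + 2]
        offset = pos - start
        mut = germ[:offset] + variant.alt + germ[offset + 1:]
        if _register_matches_ngg(mut) and not _register_matches_ngg(germ):
            events.append(design_sgrna(reference, PamEvent(variant, Strand.PLUS, start)))
        if _register_matches_ccn(mut) and not _register_matches_ccn(germ):
            events.append(design_sgrna(reference, PamEvent(variant, Strand.MINUS, start)))
    return events


def design_sgrna(reference: dict[str, str], event: PamEvent) -> PamEvent:
    """Fill in the 20-base protospacer 5' of the PAM and its GC content.

    For plus-strand events the protospacer is the 20 reference bases
    immediately left of the register; for minus-strand events it is the
    reverse complement of the 20 bases immediately right. Events too close
    to a contig end are flagged undesignable, not dropped.
    """
    seq = reference[event.variant.contig]
    start = event.pam_register
    if event.strand is Strand.PLUS:
        lo = start - 1 - PROTOSPACER_LEN
        if lo < 0:
            event.designable = False
            return event
        proto = seq[lo:start - 1]
    else:
        hi = start + 2 + PROTOSPACER_LEN
        if hi > len(seq):
            event.designable = False
            return event
        proto = revcomp(seq[start + 2:hi])
    event.protospacer = proto
    event.gc_fraction = gc_fraction(proto)
    lo_gc, hi_gc = GC_OPTIMAL_RANGE
    event.gc_optimal = lo_gc <= event.gc_fraction <= hi_gc
    event.designable = True
    return event


def gc_fraction(seq: str) -> float:
    if not seq:
        raise PamTraceError("empty sequence has no GC fraction")
    return (seq.count("G") + seq.count("C")) / len(seq)


def build_gene_index(genes: list[GeneModel]) -> dict[str, tuple[IntervalTree, IntervalTree]]:
    """Per-contig interval trees over gene bodies and coding subintervals."""
    bodies: dict[str, IntervalTree] = {}
    coding: dict[str, IntervalTree] = {}
    for g in genes:
        bodies.setdefault(g.contig, IntervalTree()).addi(g.start, g.end + 1, g.name)
        for cs, ce in g.coding:
            if not (g.start <= cs <= ce <= g.end):
                raise PamTraceError(f"coding interval outside gene body for {g.name!r}")
            coding.setdefault(g.contig, IntervalTree()).addi(cs, ce + 1, g.name)
    return {c: (bodies.get(c, IntervalTree()), coding.get(c, IntervalTree()))
            for c in set(bodies) | set(coding)}


def annotate_context(event: PamEvent, genes: list[GeneModel] | dict,
                     near_window: int = DEFAULT_NEAR_WINDOW) -> GenomicContext:
    """Genomic context of the mutated base: coding, intron/near-coding, intergenic.

    ``genes`` is a list of :class:`GeneModel` or a prebuilt index from
    :func:`build_gene_index`. An empty annotation labels everything intergenic.
    """
    index = genes if isinstance(genes, dict) else build_gene_index(genes)
    pos = event.variant.pos
    trees = index.get(event.variant.contig)
    if trees is None:
        event.context = GenomicContext.INTERGENIC
        return event.context
    bodies, coding = trees
    if coding.overlaps(pos):
        event.context = GenomicContext.CODING
    elif bodies.overlaps(pos) or bodies.overlap(pos - near_window, pos + near_window + 1):
        event.context = GenomicContext.INTRON_OR_NEAR_CODING
    else:
        event.context = GenomicContext.INTERGENIC
    return event.context


def discover_pams(reference: dict[str, str], somatic: list[Variant],
                  genes: list[GeneModel] | None = None,
                  near_window: int = DEFAULT_NEAR_WINDOW) -> list[PamEvent]:
    """Scan all somatic SBS for novel PAM registers and annotate each event."""
    index = build_gene_index(genes) if genes else {}
    events: list[PamEvent] = []
    for v in somatic:
        for ev in scan_novel_pams(reference, v):
            annotate_context(ev, index, near_window)
            events.append(ev)
    log.info("discover_pams: %d somatic SBS yielded %d novel PAM events "
             "(%d variants with at least one)",
             len(somatic), len(events), len({e.variant for e in events}))
    return events
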