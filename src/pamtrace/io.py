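"""Readers, writers, the case manifest, pipeline configuration, and the
end-to-end case runner (discover -> classify -> maintain -> tree).

Formats: FASTA (Biopython), VCF v4.2 with AF/DP in FORMAT (pysam), segment
TSV with 1-based inclusive coordinates, gene BED (0-based half-open) with
optional coding subinterval columns, Newick, and TSV/JSON reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .discovery import discover_pams, somatic_subtract
from .maintenance import PresenceMatrix, define_truncal, maintenance_stats
from .model import (
    BASES,
    CopyNumberSegment,
    GeneModel,
    PamEvent,
    PamTraceError,
    SampleRole,
    Variant,
    VariantCall,
)
from .phylo import SampleTree, binary_distance, reroot_at_primary, upgma
from .zygosity import arm_summary, classify_regions, region_status_frame

log = logging.getLogger(__name__)


class StageError(PamTraceError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"pipeline stage {stage!r} failed: {detail}")
        self.stage = stage


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- VCF

def _vcf_header(sample: str, contig_lengths: dict[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig, length in contig_lengths.items():
        header.contigs.add(contig, length=length)
    header.info.add("MQ", 1, "Float", "RMS mapping quality")
    header.formats.add("AF", "A", "Float", "Allele fraction of the alternate allele")
    header.formats.add("DP", 1, "Integer", "Read depth at this position")
    header.add_sample(sample)
    return header


def write_vcf(calls: list[VariantCall], sample: str, path: str | Path,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write single-sample capture-style records (AF/DP in FORMAT, MQ in INFO)."""
    if contig_lengths is None:
        contig_lengths = {}
        for c in calls:
            contig_lengths[c.variant.contig] = max(
                contig_lengths.get(c.variant.contig, 0), c.variant.pos)
    with pysam.VariantFile(str(path), "w",
                           header=_vcf_header(sample, contig_lengths)) as vf:
        for call in sorted(calls, key=lambda c: (c.variant.contig, c.variant.pos,
                                                 c.variant.ref, c.variant.alt)):
            v = call.variant
            rec = vf.new_record(contig=v.contig, start=v.pos - 1,
                                alleles=(v.ref, v.alt))
            rec.info["MQ"] = float(call.mapping_quality)
            rec.samples[sample]["AF"] = float(call.vaf)
            rec.samples[sample]["DP"] = int(call.depth)
            vf.write(rec)


def read_vcf(path: str | Path, reference: dict[str, str] | None = None,
             sample: str | None = None) -> list[VariantCall]:
    """Parse SBS records; split multi-allelics; skip non-SBS with a logged count.

    AF is taken from FORMAT AF (or INFO AF), computed from AD when missing;
    DP from FORMAT/INFO DP. A REF disagreement with a provided reference is
    a parse error naming the record.
    """
    calls: list[VariantCall] = []
    n_skipped = 0
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise PamTraceError(f"cannot parse VCF {path}: {exc}") from exc
    with vf:
        header_samples = list(vf.header.samples)
        sname = sample or (header_samples[0] if header_samples else Path(str(path)).stem)
        for idx, rec in enumerate(vf, start=1):
            ref = rec.ref or ""
            for alt_i, alt in enumerate(rec.alts or ()):
                if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
                    n_skipped += 1
                    continue
                if reference is not None:
                    refseq = reference.get(rec.contig)
                    if refseq is None or refseq[rec.pos - 1] != ref:
                        raise PamTraceError(
                            f"{path} record {idx}: REF {ref} does not match reference "
                            f"at {rec.contig}:{rec.pos}")
                vaf, depth = _extract_af_dp(rec, header_samples, alt_i)
                if vaf is None:
                    n_skipped += 1
                    continue
                try:  # pysam raises on INFO keys absent from the header
                    mq = rec.info.get("MQ", 60.0)
                except (KeyError, ValueError):
                    mq = 60.0
                mq = float(mq[0] if isinstance(mq, tuple) else mq)
                calls.append(VariantCall(Variant(rec.contig, rec.pos, ref, alt),
                                         sname, min(max(vaf, 0.0), 1.0),
                                         int(depth or 0), mq))
    if n_skipped:
        log.info("read_vcf(%s): skipped %d non-SBS or AF-less allele records",
                 path, n_skipped)
    return calls


def _extract_af_dp(rec, header_samples: list[str], alt_i: int):
    af = dp = None
    if header_samples:
        fmt = rec.samples[header_samples[0]]
        if "AF" in fmt and fmt["AF"] is not None:
            v = fmt["AF"]
            af = v[alt_i] if isinstance(v, tuple) else v
        if "DP" in fmt and fmt["DP"] is not None:
            dp = fmt["DP"]
        if af is None and "AD" in fmt and fmt["AD"] is not None:
            ad = fmt["AD"]
            total = sum(x for x in ad if x is not None)
            if total:
                af = ad[alt_i + 1] / total
                dp = dp or total
    try:
        if af is None and "AF" in rec.info:
            v = rec.info["AF"]
            af = v[alt_i] if isinstance(v, tuple) else v
        if dp is None:
            dp = rec.info.get("DP", 0)
    except (KeyError, ValueError):  # key absent from the header definition
        dp = dp or 0
    return (None if af is None else float(af)), dp


# ---------------------------------------------------------------- segments

def write_segments(segments: list[CopyNumberSegment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\ttotal_cn\n")
        for seg in sorted(segments, key=lambda s: (s.contig, s.start)):
            fh.write(f"{seg.contig}\t{seg.start}\t{seg.end}\t{seg.total_cn}\n")


def read_segments(path: str | Path, sample: str) -> list[CopyNumberSegment]:
    df = pd.read_csv(path, sep="\t")
    required = {"contig", "start", "end", "total_cn"}
    if not required.issubset(df.columns):
        raise PamTraceError(f"segment file {path} missing columns "
                            f"{sorted(required - set(df.columns))}")
    return [CopyNumberSegment(str(r.contig), int(r.start), int(r.end),
                              int(r.total_cn), sample)
            for r in df.itertuples()]


# ---------------------------------------------------------------- genes / BED

def read_genes_bed(path: str | Path) -> list[GeneModel]:
    """Gene bodies from BED (0-based half-open); optional columns 5-6 give a
    coding subinterval (thickStart/thickEnd style)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            contig, start, end = parts[0], int(parts[1]) + 1, int(parts[2])
            name = parts[3] if len(parts) > 3 else ""
            coding: tuple[tuple[int, int], ...] = ()
            if len(parts) > 6 and parts[6] != parts[5]:
                coding = ((int(parts[5]) + 1, int(parts[6])),)
            genes.append(GeneModel(contig, start, end, name, coding))
    return genes


def write_pam_bed(events: list[PamEvent], path: str | Path) -> None:
    """PAM registers as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for ev in sorted(events, key=lambda e: (e.variant.contig, e.pam_register)):
            fh.write(f"{ev.variant.contig}\t{ev.pam_register - 1}\t"
                     f"{ev.pam_register + 2}\t{ev.id}\t0\t{ev.strand.value}\n")


def pam_table(events: list[PamEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        rows.append({
            "id": ev.id, "contig": ev.variant.contig, "pos": ev.variant.pos,
            "ref": ev.variant.ref, "alt": ev.variant.alt,
            "strand": ev.strand.value, "pam_register": ev.pam_register,
            "protospacer": ev.protospacer or "",
            "gc_fraction": "" if ev.gc_fraction is None else round(ev.gc_fraction, 4),
            "gc_optimal": bool(ev.gc_optimal) if ev.gc_optimal is not None else "",
            "designable": ev.designable,
            "context": ev.context.value if ev.context else "",
        })
    return pd.DataFrame(rows)


def write_pam_table(events: list[PamEvent], path: str | Path) -> None:
    pam_table(events).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- manifest & config

@dataclass
class ManifestEntry:
    sample: str
    role: SampleRole
    vcf: Path
    segments: Path | None


@dataclass
class CaseManifest:
    """One rapid-autopsy case: sample roles plus the files describing them."""

    case_id: str
    reference: Path
    entries: list[ManifestEntry]
    annotation: Path | None = None

    def validate(self) -> None:
        normals = [e for e in self.entries if e.role is SampleRole.NORMAL]
        tumors = [e for e in self.entries if e.role is not SampleRole.NORMAL]
        if len(normals) != 1:
            raise PamTraceError(f"manifest must contain exactly one normal sample, "
                                f"found {len(normals)}")
        if not tumors:
            raise PamTraceError("manifest contains no tumor samples")
        names = [e.sample for e in self.entries]
        if len(set(names)) != len(names):
            raise PamTraceError("duplicate sample names in manifest")
        for p in [self.reference] + [e.vcf for e in self.entries] \
                + [e.segments for e in self.entries if e.segments]:
            if not Path(p).exists():
                raise PamTraceError(f"manifest path does not exist: {p}")

    @classmethod
    def load(cls, path: str | Path, reference: str | Path | None = None,
             annotation: str | Path | None = None,
             case_id: str | None = None) -> "CaseManifest":
        path = Path(path)
        base = path.parent
        df = pd.read_csv(path, sep="\t")
        entries = []
        for r in df.itertuples():
            seg = getattr(r, "segments", None)
            entries.append(ManifestEntry(
                sample=str(r.sample), role=SampleRole(str(r.role)),
                vcf=base / str(r.vcf),
                segments=(base / str(seg)) if isinstance(seg, str) else None))
        ref = Path(reference) if reference else base / "reference.fa"
        manifest = cls(case_id=case_id or base.name, reference=ref, entries=entries,
                       annotation=Path(annotation) if annotation else None)
        manifest.validate()
        return manifest


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, with its default."""

    min_mq: float = 20.0          # variant filter: mapping quality
    min_depth: int = 10           # variant filter: read depth
    min_af: float = 0.05          # variant filter: allele fraction
    presence_vaf_cutoff: float = 0.05   # capture presence call
    min_presence_depth: int = 20        # below this: no_coverage
    loh_vaf_threshold: float = 0.95     # high-VAF LOH call
    gc_min: float = 0.40          # optimal sgRNA GC window (inclusive)
    gc_max: float = 0.80
    near_window: int = 2000       # "near coding" distance in bases
    min_mean_depth: float = 20.0  # sample QC

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise PamTraceError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------- run_case

@dataclass
class CaseReport:
    """Bundle of everything the end-to-end pipeline produces for one case."""

    manifest: CaseManifest
    config: PipelineConfig
    somatic: list[Variant]
    pam_events: list[PamEvent]
    matrix: PresenceMatrix
    truncal: set[str]
    maintenance: object
    region_status: list
    arm_table: pd.DataFrame
    tree: SampleTree | None
    summary: dict = field(default_factory=dict)


def run_case(manifest: CaseManifest, config: PipelineConfig | None = None,
             outdir: str | Path | None = None,
             arms: list[tuple[str, str, int, int]] | None = None) -> CaseReport:
    """Execute the full pipeline on one case manifest.

    Stages: somatic subtraction per tumor sample (union across primaries and
    metastases used for discovery), novel-PAM scanning and annotation,
    presence matrix at PAM sites, truncal definition and maintenance
    statistics, region LOH classification and per-arm summaries, and the
    UPGMA sample tree re-rooted at the founder-most primary. Outputs are
    deterministic for fixed inputs and configuration.
    """
    config = config or PipelineConfig()
    manifest.validate()

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PamTraceError as exc:
            raise StageError(name, str(exc)) from exc

    reference = stage("read_reference", read_fasta, manifest.reference)
    calls: dict[str, list[VariantCall]] = {}
    roles: dict[str, SampleRole] = {}
    segments: dict[str, list[CopyNumberSegment]] = {}
    for entry in manifest.entries:
        calls[entry.sample] = stage(f"read_vcf:{entry.sample}", read_vcf,
                                    entry.vcf, sample=entry.sample)
        roles[entry.sample] = entry.role
        if entry.segments:
            segments[entry.sample] = stage(f"read_segments:{entry.sample}",
                                           read_segments, entry.segments, entry.sample)
    normal = next(e.sample for e in manifest.entries if e.role is SampleRole.NORMAL)
    tumors = [e.sample for e in manifest.entries if e.role is not SampleRole.NORMAL]

    somatic: set[Variant] = set()
    for t in tumors:
        somatic |= set(stage(f"somatic_subtract:{t}", somatic_subtract,
                             calls[t], calls[normal], config.min_mq,
                             config.min_depth, config.min_af))
    somatic_sorted = sorted(somatic)
    genes = (stage("read_annotation", read_genes_bed, manifest.annotation)
             if manifest.annotation else None)
    events = stage("discover_pams", discover_pams, reference, somatic_sorted,
                   genes, config.near_window)
    pam_df = pam_table(events)
    site_ids = sorted(set(pam_df["id"])) if len(pam_df) else []
    positions = pam_df.drop_duplicates("id")[["id", "contig", "pos"]] if len(pam_df) \
        else pd.DataFrame(columns=["id", "contig", "pos"])

    obs = {
        s: {c.variant.id: (c.vaf, c.depth) for c in calls[s]
            if c.variant.id in set(site_ids)}
        for s in calls
    }
    matrix = stage("presence_matrix", PresenceMatrix.from_calls, site_ids, obs,
                   roles, config.presence_vaf_cutoff, config.min_presence_depth)
    truncal = stage("define_truncal", define_truncal, matrix)
    report = stage("maintenance_stats", maintenance_stats, matrix, truncal)
    statuses = stage("classify_regions", classify_regions, positions, matrix,
                     segments, arms, config.loh_vaf_threshold, truncal)
    arm_df = stage("arm_summary", arm_summary, positions, matrix, segments,
                   truncal, arms)

    tree = None
    if len(tumors) >= 2 and site_ids:
        tumor_matrix = PresenceMatrix(
            entries=matrix.entries[tumors], roles=roles,
            vaf=matrix.vaf[tumors], depth=matrix.depth[tumors],
            presence_vaf_cutoff=matrix.presence_vaf_cutoff,
            min_presence_depth=matrix.min_presence_depth)
        distances = stage("binary_distance", binary_distance, tumor_matrix)
        tree = stage("upgma", upgma, distances)
        tree = stage("reroot", reroot_at_primary, tree, tumor_matrix)

    summary = {
        "case_id": manifest.case_id,
        "pamtrace_version": __version__,
        "config_hash": config.hash(),
        "n_somatic_sbs": len(somatic_sorted),
        "n_pam_events": len(events),
        "n_pam_sites": len(site_ids),
        "n_truncal_pams": len(truncal),
        "percent_truncal_per_metastasis":
            {k: _r(v) for k, v in report.percent_truncal.items()},
        "mean_percent_truncal": _r(report.mean_percent_truncal),
        "sem_percent_truncal": _r(report.sem_percent_truncal),
        "mean_percent_maintained": _r(report.mean_percent_maintained),
        "sem_percent_maintained": _r(report.sem_percent_maintained),
        "percent_shared_all_lesions": _r(report.percent_shared_all),
        "n_no_coverage_cells": report.n_no_coverage_cells,
        "region_labels": {st.region: st.label.value for st in statuses},
    }
    bundle = CaseReport(manifest=manifest, config=config, somatic=somatic_sorted,
                        pam_events=events, matrix=matrix, truncal=truncal,
                        maintenance=report, region_status=statuses,
                        arm_table=arm_df, tree=tree, summary=summary)
    if outdir is not None:
        _write_outputs(bundle, Path(outdir))
    return bundle


def _r(x) -> float | None:
    try:
        return None if x is None or pd.isna(x) else round(float(x), 4)
    except TypeError:
        return None


def _write_outputs(bundle: CaseReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_pam_table(bundle.pam_events, outdir / "pams.tsv")
    write_pam_bed(bundle.pam_events, outdir / "targets.bed")
    bundle.matrix.entries.to_csv(outdir / "presence_matrix.tsv", sep="\t",
                                 index_label="id")
    region_status_frame(bundle.region_status).to_csv(
        outdir / "region_status.tsv", sep="\t", index=False)
    bundle.arm_table.to_csv(outdir / "arm_summary.tsv", sep="\t", index=False)
    rep = bundle.maintenance
    rep.percent_truncal.to_frame().to_csv(outdir / "percent_truncal.tsv", sep="\t",
                                          index_label="metastasis")
    rep.percent_maintained.to_frame().to_csv(outdir / "percent_maintained.tsv",
                                             sep="\t", index_label="id")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(bundle.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if bundle.tree is not None:
        (outdir / "tree.nwk").write_text(bundle.tree.newick + "\n")
    log_lines = [
        f"pamtrace {__version__}",
        f"case {bundle.manifest.case_id}",
        f"config_hash {bundle.config.hash()}",
        f"config {json.dumps(asdict(bundle.config), sort_keys=True)}",
        f"n_somatic {len(bundle.somatic)}",
        f"n_pam_events {len(bundle.pam_events)}",
        f"n_truncal {len(bundle.truncal)}",
        f"n_no_coverage_cells {bundle.maintenance.n_no_coverage_cells}",
    ]
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
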