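"""VAF / copy-number / zygosity model and LOH classification.

The expected VAF of a somatic variant carried by ``m`` of ``cn`` tumor
copies in a sample of tumor purity ``p`` is

    VAF = m * p / (cn * p + 2 * (1 - p))

(the admixed normal contributes two reference copies). At purity 1 this is
m/cn: 1/1 for hemizygous variants in haploid LOH, 1/2 for heterozygous
diploid, 1/3 and 2/3 for triploid. A sample/region is called LOH when its
copy number is 1 or when the mean VAF of its presence-called PAMs reaches
the high-VAF threshold (default 0.95), which also captures copy-neutral
LOH at CN 2. Regions are then labeled across the cohort: truncal LOH (LOH
in every informative tumor sample), private LOH (some but not all), or
retained heterozygous.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from collections import Counter

import pandas as pd

from .model import (
    CopyNumberSegment,
    PamTraceError,
    RegionLabel,
    RegionZygosityStatus,
    SampleRole,
    ZygosityState,
)
from .maintenance import NO_COVERAGE, PRESENT, PresenceMatrix

log = logging.getLogger(__name__)

DEFAULT_LOH_VAF_THRESHOLD = 0.95
DEFAULT_CN = 2  # assigned (with a warning) to PAMs with no covering segment


def expected_vaf(m: int, cn: int, purity: float = 1.0) -> float:
    """Expected variant allele fraction for m mutant copies out of cn total."""
    if not 0.0 < purity <= 1.0:
        raise PamTraceError(f"purity out of (0,1]: {purity}")
    if m < 0 or cn < 0 or m > cn:
        raise PamTraceError(f"require 0 <= m <= cn, got m={m}, cn={cn}")
    denom = cn * purity + 2.0 * (1.0 - purity)
    if denom == 0.0:
        return 0.0
    return m * purity / denom


def classify_pam_zygosity(vaf: float | None, cn: int | None = None,
                          loh_vaf_threshold: float = DEFAULT_LOH_VAF_THRESHOLD,
                          present: bool = True) -> ZygosityState:
    """Zygosity of a single presence-called PAM in a single sample.

    A PAM absent from the sample is UNINFORMATIVE; otherwise VAF at or above
    the high-VAF threshold indicates LOH and anything lower heterozygosity.
    """
    if not present or vaf is None:
        return ZygosityState.UNINFORMATIVE
    if not 0.0 <= vaf <= 1.0:
        raise PamTraceError(f"VAF out of [0,1]: {vaf}")
    return ZygosityState.LOH if vaf >= loh_vaf_threshold else ZygosityState.HET


def classify_region_recurrence(states: dict[str, ZygosityState],
                               region: str = "") -> RegionZygosityStatus:
    """Cohort label for one region from its per-tumor-sample zygosity states."""
    informative = {s: st for s, st in states.items()
                   if st is not ZygosityState.UNINFORMATIVE}
    if len(informative) < 2:
        log.warning("region %s has %d informative sample(s); label UNINFORMATIVE",
                    region or "<unnamed>", len(informative))
        return RegionZygosityStatus(region, dict(states), RegionLabel.UNINFORMATIVE)
    loh = [s for s, st in informative.items() if st is ZygosityState.LOH]
    if len(loh) == len(informative):
        label = RegionLabel.TRUNCAL_LOH
    elif loh:
        label = RegionLabel.PRIVATE_LOH
    else:
        label = RegionLabel.RETAINED_HET
    return RegionZygosityStatus(region, dict(states), label)


class SegmentIndex:
    """Per-sample, per-contig lookup of integer copy number at a position."""

    def __init__(self, segments: list[CopyNumberSegment]):
        self._by_contig: dict[str, tuple[list[int], list[CopyNumberSegment]]] = {}
        by_contig: dict[str, list[CopyNumberSegment]] = {}
        for seg in segments:
            by_contig.setdefault(seg.contig, []).append(seg)
        for contig, segs in by_contig.items():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start <= a.end:
                    raise PamTraceError(
                        f"overlapping segments on {contig} in sample {a.sample}")
            self._by_contig[contig] = ([s.start for s in segs], segs)
        self.n_uncovered = 0

    def cn_at(self, contig: str, pos: int, default: int = DEFAULT_CN) -> int:
        entry = self._by_contig.get(contig)
        if entry is not None:
            starts, segs = entry
            i = bisect_right(starts, pos) - 1
            if i >= 0 and segs[i].end >= pos:
                return segs[i].total_cn
        self.n_uncovered += 1
        return default


def region_sample_state(cn: int | None, mean_vaf: float | None,
                        n_covered_pams: int,
                        loh_vaf_threshold: float = DEFAULT_LOH_VAF_THRESHOLD,
                        ) -> ZygosityState:
    """LOH call for one region in one sample: CN = 1, or mean PAM VAF at the
    high-VAF threshold (copy-neutral LOH)."""
    if n_covered_pams == 0:
        return ZygosityState.UNINFORMATIVE
    if cn is not None and cn == 1:
        return ZygosityState.LOH
    if mean_vaf is not None and mean_vaf >= loh_vaf_threshold:
        return ZygosityState.LOH
    return ZygosityState.HET


def _default_regions(segments: dict[str, list[CopyNumberSegment]],
                     pam_positions: pd.DataFrame) -> list[tuple[str, str, int, int]]:
    """Whole-contig regions spanning all segments and PAM positions."""
    span: dict[str, int] = {}
    for segs in segments.values():
        for seg in segs:
            span[seg.contig] = max(span.get(seg.contig, 1), seg.end)
    for _, row in pam_positions.iterrows():
        span[row["contig"]] = max(span.get(row["contig"], 1), int(row["pos"]))
    return [(contig, contig, 1, end) for contig, end in sorted(span.items())]


def classify_regions(pam_positions: pd.DataFrame,
                     matrix: PresenceMatrix,
                     segments: dict[str, list[CopyNumberSegment]],
                     regions: list[tuple[str, str, int, int]] | None = None,
                     loh_vaf_threshold: float = DEFAULT_LOH_VAF_THRESHOLD,
                     truncal_ids: set[str] | None = None,
                     ) -> list[RegionZygosityStatus]:
    """Label every region truncal-LOH / private-LOH / retained-het.

    ``pam_positions`` needs columns id, contig, pos. ``regions`` rows are
    (name, contig, start, end), 1-based inclusive; the default is whole
    contigs. The per-sample copy number of a region is the majority CN over
    its PAM positions (finest-interval labeling aggregated by PAM-bearing
    sites); mean VAF is over presence-called PAMs only, so absent PAMs do
    not deflate LOH detection. When ``truncal_ids`` is given the VAF rule
    is evaluated over truncal PAMs only — sample-private mutations arise
    after an early copy-neutral LOH and sit at VAF 1/2, so including them
    would mask the uniformly high VAF of the truncal ones.
    """
    if regions is None:
        regions = _default_regions(segments, pam_positions)
    tumor_samples = [s for s in matrix.entries.columns
                     if matrix.roles[s] is not SampleRole.NORMAL]
    indexes = {s: SegmentIndex(segments.get(s, [])) for s in tumor_samples}
    pos_by_id = dict(zip(pam_positions["id"], pam_positions["pos"].astype(int)))
    out: list[RegionZygosityStatus] = []
    for name, contig, start, end in regions:
        sel = pam_positions[(pam_positions["contig"] == contig)
                            & (pam_positions["pos"] >= start)
                            & (pam_positions["pos"] <= end)]
        ids = [i for i in sel["id"] if i in matrix.entries.index]
        states: dict[str, ZygosityState] = {}
        for sample in tumor_samples:
            if not ids:
                states[sample] = ZygosityState.UNINFORMATIVE
                continue
            ent = matrix.entries.loc[ids, sample]
            covered = ent[ent != NO_COVERAGE]
            present_ids = list(ent.index[ent == PRESENT])
            if truncal_ids is not None:
                truncal_present = [i for i in present_ids if i in truncal_ids]
                present_ids = truncal_present or present_ids
            cns = Counter(indexes[sample].cn_at(contig, pos_by_id[i])
                          for i in covered.index)
            modal_cn = min((cn for cn, k in cns.items()
                            if k == max(cns.values())), default=None)
            mean_vaf = None
            if present_ids and matrix.vaf is not None:
                mean_vaf = float(matrix.vaf.loc[present_ids, sample].mean())
            states[sample] = region_sample_state(
                modal_cn, mean_vaf, len(covered), loh_vaf_threshold)
        out.append(classify_region_recurrence(states, region=name))
    n_uncovered = sum(ix.n_uncovered for ix in indexes.values())
    if n_uncovered:
        log.warning("%d PAM/sample lookups had no covering CN segment; "
                    "assigned diploid default CN=%d", n_uncovered, DEFAULT_CN)
    return out


def arm_summary(pam_positions: pd.DataFrame,
                matrix: PresenceMatrix,
                segments: dict[str, list[CopyNumberSegment]],
                truncal_ids: set[str],
                regions: list[tuple[str, str, int, int]] | None = None,
                ) -> pd.DataFrame:
    """Per-arm, per-sample mean VAF, length-weighted mean CN, and percent of
    the case's truncal PAMs on the arm that are present in the sample.

    Arms with no PAMs are excluded. Returns a tidy frame with columns
    region, sample, n_pams, mean_vaf, mean_cn, percent_maintained.
    """
    if regions is None:
        regions = _default_regions(segments, pam_positions)
    tumor_samples = [s for s in matrix.entries.columns
                     if matrix.roles[s] is not SampleRole.NORMAL]
    rows = []
    for name, contig, start, end in regions:
        sel = pam_positions[(pam_positions["contig"] == contig)
                            & (pam_positions["pos"] >= start)
                            & (pam_positions["pos"] <= end)]
        ids = [i for i in sel["id"] if i in matrix.entries.index]
        if not ids:
            continue
        truncal_here = [i for i in ids if i in truncal_ids]
        for sample in tumor_samples:
            ent = matrix.entries.loc[ids, sample]
            present_ids = list(ent.index[ent == PRESENT])
            mean_vaf = (float(matrix.vaf.loc[present_ids, sample].mean())
                        if present_ids and matrix.vaf is not None else float("nan"))
            mean_cn = _weighted_cn(segments.get(sample, []), contig, start, end)
            tr = matrix.entries.loc[truncal_here, sample] if truncal_here else pd.Series(dtype=object)
            tr_cov = tr[tr != NO_COVERAGE]
            pct = (100.0 * float((tr_cov == PRESENT).sum()) / len(tr_cov)
                   if len(tr_cov) else float("nan"))
            rows.append({"region": name, "sample": sample, "n_pams": len(ids),
                         "mean_vaf": mean_vaf, "mean_cn": mean_cn,
                         "percent_maintained": pct})
    return pd.DataFrame(rows)


def _weighted_cn(segments: list[CopyNumberSegment], contig: str,
                 start: int, end: int) -> float:
    num = den = 0.0
    for seg in segments:
        if seg.contig != contig:
            continue
        ov = min(seg.end, end) - max(seg.start, start) + 1
        if ov > 0:
            num += seg.total_cn * ov
            den += ov
    return num / den if den else float("nan")


def region_status_frame(statuses: list[RegionZygosityStatus]) -> pd.DataFrame:
    rows = []
    for st in statuses:
        row = {"region": st.region, "label": st.label.value}
        for sample, state in st.sample_states.items():
            row[f"state_{sample}"] = state.value
        rows.append(row)
    return pd.DataFrame(rows)
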