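"""Presence matrix, truncal definition, and PAM maintenance statistics.

Presence of a PAM-creating variant in a sample is called from capture-style
evidence: present iff depth >= ``min_depth`` and VAF >= ``cutoff`` (default
5%, just above background artifact noise); sites with insufficient depth are
``no_coverage`` and are excluded from both numerator and denominator of any
statistic they would enter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import PamTraceError, SampleRole, VariantCall

log = logging.getLogger(__name__)

PRESENT = "present"
ABSENT = "absent"
NO_COVERAGE = "no_coverage"


def call_presence(call: VariantCall | tuple[float, int] | None,
                  cutoff: float = 0.05, min_depth: int = 20) -> str:
    """Classify one site/sample observation as present / absent / no_coverage.

    ``call`` may be a :class:`VariantCall`, a ``(vaf, depth)`` pair, or None
    (no observation at all, treated as no_coverage).
    """
    if call is None:
        return NO_COVERAGE
    if isinstance(call, VariantCall):
        vaf, depth = call.vaf, call.depth
    else:
        vaf, depth = call
    if depth < min_depth:
        return NO_COVERAGE
    return PRESENT if vaf >= cutoff else ABSENT


@dataclass
class PresenceMatrix:
    """PAM x sample presence matrix with the evidence it was called from.

    ``entries`` holds the categorical calls; ``vaf`` and ``depth`` keep the
    underlying evidence so downstream zygosity classification can reuse it.
    """

    entries: pd.DataFrame  # index: variant ids; columns: samples; values PRESENT/ABSENT/NO_COVERAGE
    roles: dict[str, SampleRole]
    vaf: pd.DataFrame | None = None
    depth: pd.DataFrame | None = None
    presence_vaf_cutoff: float = 0.05
    min_presence_depth: int = 20

    def __post_init__(self) -> None:
        missing = set(self.entries.columns) - set(self.roles)
        if missing:
            raise PamTraceError(f"samples without a role: {sorted(missing)}")

    def samples_with_role(self, role: SampleRole) -> list[str]:
        return [s for s in self.entries.columns if self.roles[s] is role]

    @property
    def normal(self) -> str | None:
        normals = self.samples_with_role(SampleRole.NORMAL)
        return normals[0] if normals else None

    @property
    def primaries(self) -> list[str]:
        return self.samples_with_role(SampleRole.PRIMARY)

    @property
    def metastases(self) -> list[str]:
        return self.samples_with_role(SampleRole.METASTASIS)

    @classmethod
    def from_calls(cls, site_ids: list[str],
                   calls: dict[str, dict[str, tuple[float, int]]],
                   roles: dict[str, SampleRole],
                   cutoff: float = 0.05, min_depth: int = 20) -> "PresenceMatrix":
        """Build the matrix for ``site_ids`` from per-sample (vaf, depth) maps."""
        samples = list(calls)
        vaf_cols, dep_cols, ent_cols = {}, {}, {}
        for sample, obs in calls.items():
            v = np.array([obs.get(sid, (np.nan, -1))[0] for sid in site_ids], dtype=float)
            d = np.array([obs.get(sid, (np.nan, -1))[1] for sid in site_ids], dtype=int)
            ent = np.where(d < min_depth, NO_COVERAGE,
                           np.where(np.nan_to_num(v, nan=-1.0) >= cutoff, PRESENT, ABSENT))
            vaf_cols[sample], dep_cols[sample], ent_cols[sample] = v, np.maximum(d, 0), ent
        return cls(entries=pd.DataFrame(ent_cols, index=site_ids, dtype=object),
                   roles=dict(roles),
                   vaf=pd.DataFrame(vaf_cols, index=site_ids),
                   depth=pd.DataFrame(dep_cols, index=site_ids),
                   presence_vaf_cutoff=cutoff, min_presence_depth=min_depth)


def define_truncal(matrix: PresenceMatrix) -> set[str]:
    """Truncal PAM ids: present in any primary and absent in the matched normal.

    Cases without a primary sample fall back to the multi-metastasis rule:
    truncal = present in more than one metastasis (and absent in normal).
    """
    normal = matrix.normal
    if normal is None:
        raise PamTraceError("presence matrix has no normal sample")
    primaries, mets = matrix.primaries, matrix.metastases
    if not primaries and not mets:
        raise PamTraceError("presence matrix has no tumor samples")
    ent = matrix.entries
    in_normal_absent = ent[normal] == ABSENT
    if primaries:
        in_tumor = (ent[primaries] == PRESENT).any(axis=1)
    else:
        in_tumor = (ent[mets] == PRESENT).sum(axis=1) >= 2
    return set(ent.index[in_tumor & in_normal_absent])


@dataclass
class MaintenanceReport:
    """Per-case maintenance statistics over the truncal PAM set."""

    truncal_pam_ids: set[str]
    percent_truncal: pd.Series  # per metastasis
    percent_maintained: pd.Series  # per truncal PAM
    percent_shared_all: float
    mean_percent_truncal: float
    sem_percent_truncal: float
    mean_percent_maintained: float
    sem_percent_maintained: float
    n_no_coverage_cells: int
    undefined: bool = False
    notes: list[str] = field(default_factory=list)


def _sem(values: np.ndarray) -> float:
    if len(values) < 2:
        return float("nan")
    return float(stats.sem(values))


def maintenance_stats(matrix: PresenceMatrix, truncal: set[str]) -> MaintenanceReport:
    """Percent truncal per metastasis, percent maintained per PAM, shared-by-all.

    no_coverage cells are dropped from both numerator and denominator of the
    statistic they would enter; the affected cell count is reported.
    """
    mets = matrix.metastases
    if not mets:
        raise PamTraceError("maintenance statistics require at least one metastasis")
    ids = sorted(truncal & set(matrix.entries.index))
    if not ids:
        log.warning("empty truncal set: maintenance percentages undefined")
        return MaintenanceReport(
            truncal_pam_ids=set(), percent_truncal=pd.Series(dtype=float),
            percent_maintained=pd.Series(dtype=float), percent_shared_all=float("nan"),
            mean_percent_truncal=float("nan"), sem_percent_truncal=float("nan"),
            mean_percent_maintained=float("nan"), sem_percent_maintained=float("nan"),
            n_no_coverage_cells=0, undefined=True,
            notes=["truncal set empty; percentages undefined"])
    sub = matrix.entries.loc[ids]
    met_block = sub[mets]
    n_nc = int((met_block == NO_COVERAGE).to_numpy().sum())

    pct_truncal = {}
    for met in mets:
        col = met_block[met]
        covered = col != NO_COVERAGE
        denom = int(covered.sum())
        pct_truncal[met] = 100.0 * (col[covered] == PRESENT).sum() / denom if denom else float("nan")
    pct_truncal = pd.Series(pct_truncal, name="percent_truncal")

    covered = met_block != NO_COVERAGE
    n_cov = covered.sum(axis=1)
    n_present = (met_block == PRESENT).sum(axis=1)
    pct_maintained = (100.0 * n_present / n_cov.where(n_cov > 0)).rename("percent_maintained")

    # shared-by-all: present in every metastasis and every primary; rows with
    # any no_coverage among those columns are excluded from both sides
    cols = mets + matrix.primaries
    block = sub[cols]
    informative = (block != NO_COVERAGE).all(axis=1)
    denom = int(informative.sum())
    shared = float("nan")
    if denom:
        shared = 100.0 * float((block[informative] == PRESENT).all(axis=1).sum()) / denom

    pt = pct_truncal.dropna().to_numpy()
    pm = pct_maintained.dropna().to_numpy()
    return MaintenanceReport(
        truncal_pam_ids=set(ids),
        percent_truncal=pct_truncal,
        percent_maintained=pct_maintained,
        percent_shared_all=shared,
        mean_percent_truncal=float(np.mean(pt)) if len(pt) else float("nan"),
        sem_percent_truncal=_sem(pt),
        mean_percent_maintained=float(np.mean(pm)) if len(pm) else float("nan"),
        sem_percent_maintained=_sem(pm),
        n_no_coverage_cells=n_nc)


def depth_qc(mean_depths: dict[str, float], percent_truncal: dict[str, float],
             min_mean_depth: float = 20.0) -> tuple[set[str], pd.DataFrame]:
    """Exclude samples whose mean capture depth falls below the threshold.

    Returns the included sample set plus the depth-vs-percent-truncal table
    for plotting/manual review. A sample with adequate depth but depressed
    percent truncal (e.g. low tumor cellularity) is retained but visible in
    the table.
    """
    rows = []
    included = set()
    for sample, depth in mean_depths.items():
        ok = depth >= min_mean_depth
        if ok:
            included.add(sample)
        rows.append({"sample": sample, "mean_depth": depth,
                     "percent_truncal": percent_truncal.get(sample, float("nan")),
                     "included": ok})
    return included, pd.DataFrame(rows)


def compare_groups(groups: dict[str, list[float]], method: str = "auto",
                   ) -> tuple[float, float, str]:
    """Compare per-metastasis percent-truncal values across cases.

    ``auto`` dispatches to Mann-Whitney for two groups and Kruskal-Wallis for
    three or more; ``anova`` forces one-way ANOVA. Returns (statistic, p,
    method name).
    """
    if len(groups) < 2:
        raise PamTraceError("need at least two groups to compare")
    for name, values in groups.items():
        if len(values) < 1:
            raise PamTraceError(f"group {name!r} is empty")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if method == "anova":
        stat, p = stats.f_oneway(*arrays)
        return float(stat), float(p), "one-way ANOVA"
    if method == "auto":
        method = "mannwhitney" if len(arrays) == 2 else "kruskal"
    if method == "mannwhitney":
        if len(arrays) != 2:
            raise PamTraceError("Mann-Whitney requires exactly two groups")
        stat, p = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
        return float(stat), float(p), "Mann-Whitney U"
    if method == "kruskal":
        pooled = np.concatenate(arrays)
        if np.all(pooled == pooled[0]):
            # all observations identical: no evidence of any difference
            return 0.0, 1.0, "Kruskal-Wallis"
        stat, p = stats.kruskal(*arrays)
        return float(stat), float(p), "Kruskal-Wallis"
    raise PamTraceError(f"unknown method {method!r}")


def sample_mean_depths(depth: pd.DataFrame) -> dict[str, float]:
    """Mean per-sample depth over captured PAM positions."""
    return {s: float(depth[s].mean()) if len(depth) else math.nan for s in depth.columns}
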