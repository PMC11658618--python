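import numpy as np
import pandas as pd
import pytest

from pamtrace.maintenance import (
    ABSENT,
    NO_COVERAGE,
    PRESENT,
    PresenceMatrix,
    call_presence,
    compare_groups,
    define_truncal,
    depth_qc,
    maintenance_stats,
    sample_mean_depths,
)
from pamtrace.model import PamTraceError, SampleRole


@pytest.mark.parametrize("vaf,depth,expect", [
    (0.5, 100, PRESENT),
    (0.04, 100, ABSENT),       # below the 5% cutoff
    (0.05, 100, PRESENT),      # cutoff inclusive
    (0.5, 5, NO_COVERAGE),     # insufficient depth is never "absent"
    (0.0, 20, ABSENT),         # depth boundary inclusive
    (0.0, 19, NO_COVERAGE),
])
def test_presence_call_thresholds(vaf, depth, expect):
    assert call_presence((vaf, depth)) == expect
    assert call_presence(None) == NO_COVERAGE


def _matrix(rows, roles, ids=None):
    ids = ids or [f"v{i}" for i in range(len(rows))]
    ent = pd.DataFrame(rows, index=ids, columns=list(roles))
    return PresenceMatrix(entries=ent, roles=roles)


ROLES4 = {"N": SampleRole.NORMAL, "P1": SampleRole.PRIMARY,
          "P2": SampleRole.PRIMARY, "M1": SampleRole.METASTASIS}


def test_truncal_requires_any_primary_and_normal_absence():
    m = _matrix([
        [ABSENT, PRESENT, ABSENT, PRESENT],   # in one of two primaries -> truncal
        [PRESENT, PRESENT, PRESENT, PRESENT],  # germline: in normal -> excluded
        [ABSENT, ABSENT, ABSENT, PRESENT],     # metastasis-private -> not truncal
        [NO_COVERAGE, PRESENT, PRESENT, PRESENT],  # normal not confirmably absent
    ], ROLES4)
    assert define_truncal(m) == {"v0"}


def test_truncal_fallback_without_primary_needs_two_metastases():
    roles = {"N": SampleRole.NORMAL, "M1": SampleRole.METASTASIS,
             "M2": SampleRole.METASTASIS, "M3": SampleRole.METASTASIS}
    m = _matrix([
        [ABSENT, PRESENT, PRESENT, ABSENT],   # two metastases -> truncal
        [ABSENT, PRESENT, ABSENT, ABSENT],    # only one -> private
        [PRESENT, PRESENT, PRESENT, PRESENT],  # germline
    ], roles)
    assert define_truncal(m) == {"v0"}


def test_truncal_without_normal_or_tumors_errors():
    with pytest.raises(PamTraceError, match="normal"):
        define_truncal(_matrix([[PRESENT]], {"M1": SampleRole.METASTASIS}))
    with pytest.raises(PamTraceError, match="tumor"):
        define_truncal(_matrix([[ABSENT]], {"N": SampleRole.NORMAL}))


def test_percent_truncal_arithmetic():
    roles = {"N": SampleRole.NORMAL, "P1": SampleRole.PRIMARY,
             "M1": SampleRole.METASTASIS}
    rows = [[ABSENT, PRESENT, PRESENT]] * 9 + [[ABSENT, PRESENT, ABSENT]]
    m = _matrix(rows, roles)
    report = maintenance_stats(m, define_truncal(m))
    assert report.percent_truncal["M1"] == pytest.approx(90.0)
    assert report.percent_shared_all == pytest.approx(90.0)


def test_no_coverage_cells_excluded_from_both_sides():
    roles = {"N": SampleRole.NORMAL, "P1": SampleRole.PRIMARY,
             "M1": SampleRole.METASTASIS, "M2": SampleRole.METASTASIS}
    rows = [
        [ABSENT, PRESENT, PRESENT, PRESENT],
        [ABSENT, PRESENT, NO_COVERAGE, PRESENT],  # M1 has no evidence here
        [ABSENT, PRESENT, ABSENT, PRESENT],
    ]
    m = _matrix(rows, roles)
    report = maintenance_stats(m, define_truncal(m))
    assert report.percent_truncal["M1"] == pytest.approx(50.0)  # 1 of 2 covered
    assert report.percent_truncal["M2"] == pytest.approx(100.0)
    assert report.n_no_coverage_cells == 1
    # the no_coverage row is excluded from shared-by-all entirely
    assert report.percent_shared_all == pytest.approx(50.0)


def test_empty_truncal_set_is_flagged_not_silent_zero():
    roles = {"N": SampleRole.NORMAL, "P1": SampleRole.PRIMARY,
             "M1": SampleRole.METASTASIS}
    m = _matrix([[PRESENT, PRESENT, PRESENT]], roles)
    report = maintenance_stats(m, define_truncal(m))
    assert report.undefined
    assert np.isnan(report.percent_shared_all)


def test_maintenance_requires_a_metastasis():
    roles = {"N": SampleRole.NORMAL, "P1": SampleRole.PRIMARY}
    m = _matrix([[ABSENT, PRESENT]], roles)
    with pytest.raises(PamTraceError, match="metastasis"):
        maintenance_stats(m, {"v0"})


def test_maintenance_statistics_match_truth_recomputation(small_pipeline):
    """Percent truncal, percent maintained, and shared-by-all recomputed
    independently from the simulator's ground-truth mutant copy counts."""
    p = small_pipeline
    case, truth = p["case"], p["truth"]
    report = maintenance_stats(p["matrix"], p["truncal"])
    mets = [s for s, r in case.roles.items() if r is SampleRole.METASTASIS]
    truncal = sorted(p["truncal"])
    for met in mets:
        expect = 100.0 * sum(truth[i].m[met] > 0 for i in truncal) / len(truncal)
        assert report.percent_truncal[met] == pytest.approx(expect)
    for pam in truncal:
        expect = 100.0 * sum(truth[pam].m[met] > 0 for met in mets) / len(mets)
        assert report.percent_maintained[pam] == pytest.approx(expect)
    shared = sum(all(truth[i].m[s] > 0 for s in mets + ["P1"]) for i in truncal)
    assert report.percent_shared_all == pytest.approx(100.0 * shared / len(truncal))


def test_truncal_loh_pams_fully_maintained(small_pipeline):
    p = small_pipeline
    case, truth = p["case"], p["truth"]
    report = maintenance_stats(p["matrix"], p["truncal"])
    loh_pams = [i for i in p["truncal"]
                if truth[i].variant.contig in case.config.truncal_loh_contigs]
    assert loh_pams
    assert (report.percent_maintained[loh_pams] == 100.0).all()


def test_shared_all_bounded_by_min_percent_truncal(small_pipeline):
    report = maintenance_stats(small_pipeline["matrix"], small_pipeline["truncal"])
    assert report.percent_shared_all <= report.percent_truncal.min() + 1e-9


def test_removing_a_metastasis_never_decreases_shared_all(small_pipeline):
    p = small_pipeline
    full = maintenance_stats(p["matrix"], p["truncal"]).percent_shared_all
    m = p["matrix"]
    for met in m.metastases:
        keep = [c for c in m.entries.columns if c != met]
        sub = PresenceMatrix(entries=m.entries[keep],
                             roles={s: m.roles[s] for s in keep},
                             vaf=m.vaf[keep], depth=m.depth[keep])
        assert maintenance_stats(sub, p["truncal"]).percent_shared_all >= full - 1e-9


def test_double_counting_identity_on_complete_matrices(small_pipeline):
    """With no missing cells, averaging percent-truncal over metastases and
    percent-maintained over PAMs counts the same present cells."""
    report = maintenance_stats(small_pipeline["matrix"], small_pipeline["truncal"])
    assert report.n_no_coverage_cells == 0
    assert report.mean_percent_truncal == pytest.approx(report.mean_percent_maintained)


def test_depth_qc_threshold_and_reporting(small_pipeline):
    depths = sample_mean_depths(small_pipeline["matrix"].depth)
    pct = {s: 90.0 for s in depths}
    included, table = depth_qc(depths, pct, min_mean_depth=20.0)
    assert included == set(depths)  # noise-free sim emits full nominal depth
    included2, table2 = depth_qc({**depths, "bad": 0.0}, pct, min_mean_depth=20.0)
    assert "bad" not in included2
    assert bool(table2.loc[table2["sample"] == "bad", "included"].iloc[0]) is False


def test_low_purity_sample_flagged_by_depressed_percent_truncal():
    """A low-cellularity metastasis keeps adequate depth but loses presence
    calls: it stays in the QC-included set yet shows clearly depressed
    percent truncal in the review table."""
    from pamtrace.simulate import SimulationConfig, simulate_case

    cfg = SimulationConfig(n_contigs=4, contig_length=6000, n_germline_het=20,
                           n_truncal_sbs=300, n_private_sbs_per_met=5,
                           truncal_loh_contigs=frozenset(),
                           private_loh_events_per_met=0, n_metastases=2,
                           purity=0.08, mean_depth=100, seed=31)
    case = simulate_case(cfg)
    ids = [t.variant.id for t in case.truth if t.is_truncal]
    obs = {s: {c.variant.id: (c.vaf, c.depth) for c in case.calls[s]
               if c.variant.id in set(ids)} for s in case.samples}
    matrix = PresenceMatrix.from_calls(ids, obs, case.roles)
    # at purity 0.08 a het truncal SBS sits at expected VAF ~0.04, below cutoff
    frac_present = float((matrix.entries[case.tumor_samples] == PRESENT).mean().mean())
    assert frac_present < 0.6
    depths = sample_mean_depths(matrix.depth)
    included, table = depth_qc(depths, {s: 100 * frac_present for s in depths},
                               min_mean_depth=20.0)
    assert set(case.samples) == included  # retained, but visibly depressed


def test_compare_groups_dispatch_and_closed_forms():
    stat, p, name = compare_groups({"a": [1, 2, 3], "b": [1, 2, 3]})
    assert name == "Mann-Whitney U"
    assert stat == pytest.approx(4.5)  # U at its null mean n1*n2/2
    assert p > 0.8

    groups = {"c1": [90, 92, 91, 93], "c2": [89, 91, 92, 90],
              "c3": [60, 62, 61, 59]}  # one depressed case separates
    stat, p, name = compare_groups(groups)
    assert name == "Kruskal-Wallis" and p < 0.05

    stat, p, name = compare_groups(groups, method="anova")
    assert name == "one-way ANOVA" and p < 0.05

    with pytest.raises(PamTraceError, match="empty"):
        compare_groups({"a": [1.0], "b": []})
    with pytest.raises(PamTraceError, match="two groups"):
        compare_groups({"a": [1.0]})


def test_identical_pooled_values_give_p_one():
    stat, p, name = compare_groups({"a": [5, 5], "b": [5, 5], "c": [5, 5]})
    assert p == 1.0
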