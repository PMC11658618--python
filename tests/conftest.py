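import pandas as pd
import pytest

from pamtrace.discovery import discover_pams, somatic_subtract
from pamtrace.maintenance import PresenceMatrix, define_truncal
from pamtrace.simulate import SimulationConfig, simulate_case


@pytest.fixture(scope="session")
def small_case():
    """A noise-free case small enough for fast exact checks: 6 contigs of
    8 kb, truncal LOH on two, four metastases with two private haploid LOH
    events each, purity 1."""
    cfg = SimulationConfig(
        n_contigs=6, contig_length=8000, n_germline_het=60, n_truncal_sbs=400,
        n_private_sbs_per_met=30, truncal_loh_contigs=frozenset({"chr1", "chr2"}),
        private_loh_events_per_met=2, n_primaries=1, n_metastases=4,
        purity=1.0, mean_depth=0, seed=11)
    return simulate_case(cfg)


@pytest.fixture(scope="session")
def small_pipeline(small_case):
    """Discovery, presence matrix, and truncal set computed from the small case."""
    case = small_case
    somatic = set()
    for t in case.tumor_samples:
        somatic |= set(somatic_subtract(case.calls[t], case.calls[case.normal_sample]))
    events = discover_pams(case.genome.reference, sorted(somatic))
    site_ids = sorted({e.id for e in events})
    idset = set(site_ids)
    obs = {s: {c.variant.id: (c.vaf, c.depth) for c in case.calls[s]
               if c.variant.id in idset}
           for s in case.samples}
    matrix = PresenceMatrix.from_calls(site_ids, obs, case.roles)
    positions = pd.DataFrame(
        [{"id": e.id, "contig": e.variant.contig, "pos": e.variant.pos}
         for e in events]).drop_duplicates("id")
    truncal = define_truncal(matrix)
    return {
        "case": case, "somatic": sorted(somatic), "events": events,
        "site_ids": site_ids, "matrix": matrix, "positions": positions,
        "truncal": truncal,
        "truth": {t.variant.id: t for t in case.truth},
    }
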