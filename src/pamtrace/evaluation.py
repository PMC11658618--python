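"""End-to-end evaluation scenarios on synthetic cases.

These helpers run the discovery -> presence -> truncal -> LOH-classification
pipeline on a simulated case and measure the maintenance/loss statistics the
copy model predicts: 100% maintenance of truncal PAMs in truncal-LOH
regions, ~50% loss under private haploid LOH (one of two copies lost), and
~33% loss when a triploid contig loses one of its three copies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .discovery import discover_pams, somatic_subtract
from .maintenance import ABSENT, PRESENT, PresenceMatrix, define_truncal
from .model import RegionLabel, SampleRole
from .simulate import SimulatedCase, SimulationConfig, simulate_case
from .zygosity import classify_regions


@dataclass
class PipelineProducts:
    case: SimulatedCase
    matrix: PresenceMatrix
    positions: pd.DataFrame
    truncal: set[str]
    region_labels: dict[str, RegionLabel]
    contig_of: dict[str, str]


def run_memory_pipeline(case: SimulatedCase) -> PipelineProducts:
    """Discovery, presence matrix, truncal set, and region labels for a case."""
    normal = case.normal_sample
    somatic = set()
    for t in case.tumor_samples:
        somatic |= set(somatic_subtract(case.calls[t], case.calls[normal]))
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
    statuses = classify_regions(positions, matrix, case.segments,
                                truncal_ids=truncal)
    return PipelineProducts(
        case=case, matrix=matrix, positions=positions, truncal=truncal,
        region_labels={s.region: s.label for s in statuses},
        contig_of=dict(zip(positions["id"], positions["contig"])))


def truncal_loh_maintenance(products: PipelineProducts) -> tuple[float, int]:
    """Percent of truncal PAMs in pipeline-labeled truncal-LOH regions that
    are present in every metastasis. Returns (percent, n PAMs)."""
    p = products
    loh_contigs = {c for c, lab in p.region_labels.items()
                   if lab is RegionLabel.TRUNCAL_LOH}
    ids = [i for i in p.truncal if p.contig_of[i] in loh_contigs]
    if not ids:
        return float("nan"), 0
    block = p.matrix.entries.loc[ids, p.matrix.metastases]
    kept = int((block == PRESENT).all(axis=1).sum())
    return 100.0 * kept / len(ids), len(ids)


def _segment_cn(case: SimulatedCase) -> dict[str, dict[str, int]]:
    return {s: {seg.contig: seg.total_cn for seg in segs}
            for s, segs in case.segments.items()}


def private_haploid_loss(products: PipelineProducts) -> tuple[float, int]:
    """Pooled fraction (percent) of truncal PAMs lost in a metastasis among
    those on contigs where that metastasis underwent private haploid LOH
    (pipeline-labeled private LOH with CN 1 in the affected sample)."""
    p = products
    cn = _segment_cn(p.case)
    lost = total = 0
    for met in p.matrix.metastases:
        affected = {c for c, lab in p.region_labels.items()
                    if lab is RegionLabel.PRIVATE_LOH and cn[met].get(c) == 1}
        ids = [i for i in p.truncal if p.contig_of[i] in affected]
        col = p.matrix.entries.loc[ids, met]
        lost += int((col == ABSENT).sum())
        total += len(ids)
    return (100.0 * lost / total if total else float("nan")), total


def polyploid_single_copy_loss(products: PipelineProducts) -> tuple[float, int]:
    """Pooled fraction (percent) of truncal PAMs lost in a metastasis among
    those on triploid contigs where that metastasis dropped to two copies."""
    p = products
    cn = _segment_cn(p.case)
    primaries = [s for s, r in p.case.roles.items() if r is SampleRole.PRIMARY]
    base = cn[primaries[0]] if primaries else {}
    lost = total = 0
    for met in p.matrix.metastases:
        affected = {c for c, k in base.items() if k == 3 and cn[met].get(c) == 2}
        ids = [i for i in p.truncal if p.contig_of[i] in affected]
        col = p.matrix.entries.loc[ids, met]
        lost += int((col == ABSENT).sum())
        total += len(ids)
    return (100.0 * lost / total if total else float("nan")), total


def truncal_loh_case(seed: int) -> SimulationConfig:
    """The reference maintenance scenario: ten 100 kb contigs, 1000 truncal
    SBS, truncal LOH on three contigs, four metastases with two private
    haploid LOH events each, purity 1, noise-free."""
    return replace(SimulationConfig(), seed=seed)


def scaled_haploid_loss_case(seed: int) -> SimulationConfig:
    """Same scenario scaled so that well over 1000 truncal PAMs land on
    privately LOH contigs when pooled across the four metastases."""
    return replace(SimulationConfig(), n_truncal_sbs=15_000, seed=seed)


def triploid_loss_case(seed: int) -> SimulationConfig:
    """All contigs triploid (no truncal LOH): every private copy-loss event
    drops a triploid contig to two copies."""
    base = SimulationConfig()
    return replace(base, n_truncal_sbs=15_000, truncal_loh_contigs=frozenset(),
                   polyploid_contigs={c: 3 for c in base.contigs}, seed=seed)


def evaluate_targets(seed: int) -> dict[str, dict[str, float | int]]:
    """Recompute the three maintenance/loss statistics from fresh simulations."""
    reference = run_memory_pipeline(simulate_case(truncal_loh_case(seed)))
    v6, n6 = truncal_loh_maintenance(reference)
    scaled = run_memory_pipeline(simulate_case(scaled_haploid_loss_case(seed)))
    v7, n7 = private_haploid_loss(scaled)
    triploid = run_memory_pipeline(simulate_case(triploid_loss_case(seed + 1)))
    v8, n8 = polyploid_single_copy_loss(triploid)
    return {
        "truncal_loh_maintenance_pct": {"value": v6, "n": n6},
        "private_haploid_loss_pct": {"value": v7, "n": n7},
        "triploid_single_copy_loss_pct": {"value": v8, "n": n8},
    }
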