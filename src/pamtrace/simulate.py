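"""Clonal-evolution simulator for rapid-autopsy style cases.

Generates a haplotype-resolved toy genome, a founder (cancer-initiating)
clone carrying truncal somatic SBS, truncal LOH applied in the founder
before lineage branching, and a set of metastases that each acquire
private LOH events and private SBS. Per-sample VAFs follow the
mutant-copies / total-copies model (see :mod:`pamtrace.zygosity`), with
optional binomial read sampling.

The genome is represented per contig as a set of labeled chromosome
copies (e.g. ``A.0``, ``B.0``; polyploid contigs replicate one
haplotype). Every somatic SBS is carried by exactly one copy at birth, so
loss of a uniformly chosen copy loses the variant with probability
1/(copies) — the mechanism behind the 50%-per-copy loss rule in haploid
LOH and 1/3 loss under triploid single-copy loss. Copy-neutral LOH
duplicates the retained copy together with the variants it carries.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    BASES,
    ConfigurationError,
    CopyNumberSegment,
    RegionLabel,
    SampleRole,
    Variant,
    VariantCall,
)
from .zygosity import expected_vaf

NOISE_FREE_DEPTH = 1000  # nominal capture depth emitted when mean_depth == 0
SIMULATED_MQ = 60.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters describing one synthetic rapid-autopsy case.

    Defaults emulate a pancreatic-cancer rapid autopsy: one normal, one
    primary, four metastases descending from a founder clone with ~1000
    truncal heterozygous SBS, whole-haplotype truncal LOH on three of ten
    100 kb contigs, and two private haploid LOH events per metastasis.
    ``mean_depth = 0`` emits noise-free model VAFs at a nominal depth.
    """

    n_contigs: int = 10
    contig_length: int = 100_000
    gc_content: float = 0.41
    n_germline_het: int = 200
    n_truncal_sbs: int = 1000
    n_private_sbs_per_met: int = 50
    truncal_loh_contigs: frozenset[str] = frozenset({"chr1", "chr2", "chr3"})
    copy_neutral_loh_contigs: frozenset[str] = frozenset()
    private_loh_events_per_met: int = 2
    polyploid_contigs: dict[str, int] = field(default_factory=dict)
    n_primaries: int = 1
    n_metastases: int = 4
    n_branch_sbs: int = 0
    purity: float = 1.0
    mean_depth: int = 0
    seed: int = 42

    @property
    def contigs(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_contigs)]

    def validate(self) -> None:
        c = self
        if c.n_contigs < 1:
            raise ConfigurationError("need at least one contig")
        if c.contig_length < 50:
            raise ConfigurationError(f"contig_length must be >= 50, got {c.contig_length}")
        if not 0.0 <= c.gc_content <= 1.0:
            raise ConfigurationError(f"gc_content out of [0,1]: {c.gc_content}")
        if not 0.0 < c.purity <= 1.0:
            raise ConfigurationError(f"purity out of (0,1]: {c.purity}")
        for name in ("n_germline_het", "n_truncal_sbs", "n_private_sbs_per_met",
                     "private_loh_events_per_met", "n_primaries", "n_metastases",
                     "n_branch_sbs", "mean_depth"):
            if getattr(c, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        known = set(c.contigs)
        for group, names in (("truncal_loh_contigs", c.truncal_loh_contigs),
                             ("copy_neutral_loh_contigs", c.copy_neutral_loh_contigs),
                             ("polyploid_contigs", set(c.polyploid_contigs))):
            unknown = set(names) - known
            if unknown:
                raise ConfigurationError(f"{group} references unknown contigs: {sorted(unknown)}")
        bad_ploidy = {k: v for k, v in c.polyploid_contigs.items() if v < 3}
        if bad_ploidy:
            raise ConfigurationError(f"polyploid contigs must have total CN >= 3: {bad_ploidy}")
        clash = set(c.truncal_loh_contigs) & set(c.polyploid_contigs)
        if clash:
            # keeps the VAF classes of whole-haplotype truncal loss unambiguous
            raise ConfigurationError(
                f"truncal LOH on polyploid contigs is not supported: {sorted(clash)}")
        clash = set(c.copy_neutral_loh_contigs) & (set(c.polyploid_contigs)
                                                   | set(c.truncal_loh_contigs))
        if clash:
            raise ConfigurationError(
                f"copy-neutral LOH contigs must be plain diploid and not truncal-LOH: {sorted(clash)}")
        eligible = known - set(c.truncal_loh_contigs) - set(c.copy_neutral_loh_contigs)
        if c.private_loh_events_per_met > len(eligible):
            raise ConfigurationError(
                f"{c.private_loh_events_per_met} private LOH events per metastasis requested "
                f"but only {len(eligible)} eligible contigs exist")
        n_positions = (c.n_germline_het + c.n_truncal_sbs
                       + 2 * c.n_branch_sbs * c.n_metastases * max(c.n_metastases, 1)
                       + c.n_private_sbs_per_met * c.n_metastases)
        capacity = c.n_contigs * c.contig_length
        if n_positions > capacity // 2:
            raise ConfigurationError(
                f"cannot place {n_positions} variants on {capacity} bases "
                f"(contigs of length {c.contig_length} are too small)")


def _rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic substream: master seed + stable hash of a stage label."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(label.encode()) & 0x7FFFFFFF])


@dataclass
class Genome:
    """Reference plus two germline haplotypes per contig."""

    reference: dict[str, str]
    germline: list[Variant]  # heterozygous sites; ALT carried by haplotype B

    def haplotype(self, contig: str, hap: str) -> str:
        seq = self.reference[contig]
        if hap == "A":
            return seq
        out = list(seq)
        for v in self.germline:
            if v.contig == contig:
                out[v.pos - 1] = v.alt
        return "".join(out)


def simulate_genome(config: SimulationConfig, seed: int | None = None) -> Genome:
    """Draw an i.i.d. genome at the configured GC content and place germline hets."""
    config.validate()
    rng = _rng(config.seed if seed is None else seed, "genome")
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    reference = {
        contig: "".join(rng.choice(list(BASES), size=config.contig_length, p=probs))
        for contig in config.contigs
    }
    positions = _sample_positions(rng, config, set(), config.n_germline_het)
    germline = [_mutate(rng, reference, contig, pos) for contig, pos in positions]
    return Genome(reference=reference, germline=sorted(germline))


def _sample_positions(rng: np.random.Generator, config: SimulationConfig,
                      used: set[tuple[str, int]], n: int) -> list[tuple[str, int]]:
    """Uniform genome positions without replacement (shared ``used`` set)."""
    contigs = config.contigs
    total = config.n_contigs * config.contig_length
    out: list[tuple[str, int]] = []
    attempts = 0
    while len(out) < n:
        flat = int(rng.integers(0, total))
        key = (contigs[flat // config.contig_length], flat % config.contig_length + 1)
        attempts += 1
        if attempts > 50 * max(n, 1) + 1000:
            raise ConfigurationError(
                f"could not place {n} variants without replacement on contigs of "
                f"length {config.contig_length}")
        if key in used:
            continue
        used.add(key)
        out.append(key)
    return out


def _mutate(rng: np.random.Generator, reference: dict[str, str],
            contig: str, pos: int) -> Variant:
    ref = reference[contig][pos - 1]
    alt = str(rng.choice([b for b in BASES if b != ref]))
    return Variant(contig, pos, ref, alt)


def _hap(copy_id: str) -> str:
    return copy_id[0]


@dataclass
class _LineageNode:
    name: str
    children: list["_LineageNode"] = field(default_factory=list)
    height: float = 0.0  # 0 at leaves; join order at internal nodes (clock-like)
    span: float = 0.0  # height difference to the parent (branch length)

    @property
    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        return [leaf for ch in self.children for leaf in ch.leaves]

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        label = f"{self.name}:{self.span:g}" if self.span else self.name
        if not self.children:
            return label
        return "(" + ",".join(ch._nwk() for ch in self.children) + ")" + label


def _build_lineage(rng: np.random.Generator, mets: list[str]) -> _LineageNode:
    """Random bifurcating joins over the metastases; founder at the root.

    Join order defines node heights, so the truth lineage is ultrametric:
    branch mutation counts proportional to the height span keep the
    molecular clock that UPGMA assumes.
    """
    if not mets:
        return _LineageNode("founder")
    nodes = [_LineageNode(m) for m in mets]
    counter = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        counter += 1
        joined = _LineageNode(f"clone{counter}", [nodes[i], nodes[j]],
                              height=float(counter))
        for ch in joined.children:
            ch.span = joined.height - ch.height
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [joined]
    root = nodes[0]
    root.name = "founder"
    return root


@dataclass
class TruthRecord:
    """Ground truth for one simulated variant across all samples."""

    variant: Variant
    clone_of_origin: str  # germline | founder | clone<k> | metastasis name
    haplotype: str  # haplotype of the carrying copy at birth (A or B)
    is_truncal: bool
    m: dict[str, int]  # per-sample mutant copy count
    total_cn: dict[str, int]  # per-sample total copies of the contig
    region_label: RegionLabel


@dataclass
class SimulatedCase:
    """Everything the pipeline consumes, plus ground truth."""

    config: SimulationConfig
    genome: Genome
    roles: dict[str, SampleRole]
    calls: dict[str, list[VariantCall]]
    segments: dict[str, list[CopyNumberSegment]]
    truth: list[TruthRecord]
    region_truth: dict[str, RegionLabel]
    lineage_newick: str
    private_loh: dict[str, dict[str, str]]  # met -> contig -> lost copy id
    truncal_lost_hap: dict[str, str]  # contig -> lost haplotype (incl. copy-neutral)

    @property
    def samples(self) -> list[str]:
        return list(self.roles)

    @property
    def tumor_samples(self) -> list[str]:
        return [s for s, r in self.roles.items() if r is not SampleRole.NORMAL]

    @property
    def normal_sample(self) -> str:
        return next(s for s, r in self.roles.items() if r is SampleRole.NORMAL)

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            row = {
                "id": t.variant.id, "contig": t.variant.contig, "pos": t.variant.pos,
                "ref": t.variant.ref, "alt": t.variant.alt,
                "clone_of_origin": t.clone_of_origin, "haplotype": t.haplotype,
                "is_truncal": t.is_truncal, "region_label": t.region_label.value,
            }
            for s in self.samples:
                row[f"m_{s}"] = t.m[s]
                row[f"cn_{s}"] = t.total_cn[s]
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        from . import io as _io  # deferred: io imports pysam lazily

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        ref_path = outdir / "reference.fa"
        _io.write_fasta(self.genome.reference, ref_path)
        paths["reference"] = ref_path
        lengths = {c: len(s) for c, s in self.genome.reference.items()}
        manifest_rows = []
        for sample, role in self.roles.items():
            vcf_path = outdir / f"{sample}.vcf"
            seg_path = outdir / f"{sample}.segments.tsv"
            _io.write_vcf(self.calls[sample], sample, vcf_path, contig_lengths=lengths)
            _io.write_segments(self.segments[sample], seg_path)
            manifest_rows.append((sample, role.value, vcf_path.name, seg_path.name))
            paths[f"vcf:{sample}"] = vcf_path
            paths[f"segments:{sample}"] = seg_path
        truth_path = outdir / "truth.tsv"
        self.truth_frame().to_csv(truth_path, sep="\t", index=False)
        paths["truth"] = truth_path
        nwk_path = outdir / "lineage.nwk"
        nwk_path.write_text(self.lineage_newick + "\n")
        paths["lineage"] = nwk_path
        manifest_path = outdir / "manifest.tsv"
        with open(manifest_path, "w") as fh:
            fh.write("sample\trole\tvcf\tsegments\n")
            for row in manifest_rows:
                fh.write("\t".join(row) + "\n")
        paths["manifest"] = manifest_path
        return paths


def simulate_case(config: SimulationConfig) -> SimulatedCase:
    """Simulate one complete case: genome, founder, lineage, per-sample calls.

    See the module docstring for the copy model. Emitted VAFs are exact
    model values when ``mean_depth == 0``; otherwise depth is Poisson with
    the configured mean and alt reads are binomial.
    """
    config.validate()
    seed = config.seed
    genome = simulate_genome(config)
    used = {(v.contig, v.pos) for v in genome.germline}
    contigs = config.contigs

    # founder copy sets, pre-LOH: diploid A.0/B.0; polyploid replicates one haplotype
    ploidy_rng = _rng(seed, "ploidy")
    founder_pre: dict[str, list[str]] = {}
    for contig in contigs:
        copies = ["A.0", "B.0"]
        extra = config.polyploid_contigs.get(contig, 2) - 2
        if extra > 0:
            dup_hap = str(ploidy_rng.choice(["A", "B"]))
            copies += [f"{dup_hap}.{i + 1}" for i in range(extra)]
        founder_pre[contig] = copies

    carriers: dict[Variant, set[str]] = {}
    origin: dict[Variant, str] = {}
    birth_hap: dict[Variant, str] = {}
    for g in genome.germline:
        carriers[g] = {cp for cp in founder_pre[g.contig] if _hap(cp) == "B"}
        origin[g] = "germline"
        birth_hap[g] = "B"

    # truncal somatic SBS: one uniformly chosen founder copy each (pre-LOH)
    truncal_rng = _rng(seed, "truncal")
    truncal_variants: list[Variant] = []
    for contig, pos in _sample_positions(truncal_rng, config, used, config.n_truncal_sbs):
        v = _mutate(truncal_rng, genome.reference, contig, pos)
        cp = str(truncal_rng.choice(founder_pre[contig]))
        carriers[v] = {cp}
        origin[v] = "founder"
        birth_hap[v] = _hap(cp)
        truncal_variants.append(v)

    # truncal LOH (whole-haplotype loss) and copy-neutral LOH in the founder
    loh_rng = _rng(seed, "truncal-loh")
    founder_post = {c: list(cps) for c, cps in founder_pre.items()}
    truncal_lost_hap: dict[str, str] = {}
    for contig in sorted(config.truncal_loh_contigs):
        lost = str(loh_rng.choice(["A", "B"]))
        truncal_lost_hap[contig] = lost
        founder_post[contig] = [cp for cp in founder_pre[contig] if _hap(cp) != lost]
    for contig in sorted(config.copy_neutral_loh_contigs):
        lost = str(loh_rng.choice(["A", "B"]))
        truncal_lost_hap[contig] = lost
        retained = [cp for cp in founder_pre[contig] if _hap(cp) != lost]
        src = retained[0]
        dup = f"{_hap(src)}.cnloh"
        founder_post[contig] = retained + [dup]
        for v, cps in carriers.items():
            if v.contig == contig and src in cps:
                cps.add(dup)

    # metastasis lineage and shared branch SBS
    mets = [f"M{i + 1}" for i in range(config.n_metastases)]
    lineage = _build_lineage(_rng(seed, "lineage"), mets)
    clade: dict[str, set[str]] = {}  # lineage node -> metastases below it
    branch_rng = _rng(seed, "branch")
    stack = [lineage]
    internal_nodes: list[_LineageNode] = []
    while stack:
        node = stack.pop()
        for ch in node.children:
            stack.append(ch)
            if ch.children:  # internal, non-root branch
                internal_nodes.append(ch)
    met_extra_sbs: dict[str, int] = {}
    if config.n_branch_sbs:
        # clock-like counts: SBS per branch proportional to its height span
        stack = [lineage]
        while stack:
            node = stack.pop()
            stack.extend(node.children)
            if not node.children and node.span:
                met_extra_sbs[node.name] = round(config.n_branch_sbs * node.span)
    for node in sorted(internal_nodes, key=lambda n: n.name):
        clade[node.name] = set(node.leaves)
        n_sbs = round(config.n_branch_sbs * node.span)
        for contig, pos in _sample_positions(branch_rng, config, used, n_sbs):
            v = _mutate(branch_rng, genome.reference, contig, pos)
            cp = str(branch_rng.choice(founder_post[contig]))
            carriers[v] = {cp}
            origin[v] = node.name
            birth_hap[v] = _hap(cp)

    # per-metastasis private LOH and private SBS
    eligible = sorted(set(contigs) - set(config.truncal_loh_contigs)
                      - set(config.copy_neutral_loh_contigs))
    met_copies: dict[str, dict[str, list[str]]] = {}
    private_loh: dict[str, dict[str, str]] = {}
    for met in mets:
        rng = _rng(seed, f"met:{met}")
        copies = {c: list(cps) for c, cps in founder_post.items()}
        events: dict[str, str] = {}
        hit = [eligible[i] for i in rng.choice(len(eligible),
                                               size=config.private_loh_events_per_met,
                                               replace=False)]
        for contig in hit:
            lost_cp = str(rng.choice(copies[contig]))
            copies[contig].remove(lost_cp)
            events[contig] = lost_cp
        n_private = config.n_private_sbs_per_met + met_extra_sbs.get(met, 0)
        for contig, pos in _sample_positions(rng, config, used, n_private):
            v = _mutate(rng, genome.reference, contig, pos)
            cp = str(rng.choice(copies[contig]))
            carriers[v] = {cp}
            origin[v] = met
            birth_hap[v] = _hap(cp)
        met_copies[met] = copies
        private_loh[met] = events
        clade[met] = {met}

    # assemble samples
    roles: dict[str, SampleRole] = {"N": SampleRole.NORMAL}
    sample_copies: dict[str, dict[str, list[str]]] = {
        "N": {c: ["A.0", "B.0"] for c in contigs}  # germline is diploid everywhere
    }
    for i in range(config.n_primaries):
        name = f"P{i + 1}"
        roles[name] = SampleRole.PRIMARY
        sample_copies[name] = {c: list(cps) for c, cps in founder_post.items()}
    for met in mets:
        roles[met] = SampleRole.METASTASIS
        sample_copies[met] = met_copies[met]

    region_truth = _true_region_labels(config, roles, sample_copies)

    variants = sorted(carriers)
    vaf_rng = _rng(seed, "reads")
    calls: dict[str, list[VariantCall]] = {s: [] for s in roles}
    truth: list[TruthRecord] = []
    for v in variants:
        m_by: dict[str, int] = {}
        cn_by: dict[str, int] = {}
        for sample, role in roles.items():
            copies = sample_copies[sample][v.contig]
            cn = len(copies)
            o = origin[v]
            if o == "germline":
                in_lineage = True
            elif o == "founder":
                in_lineage = role is not SampleRole.NORMAL
            else:
                in_lineage = sample in clade[o]
            m = len(carriers[v].intersection(copies)) if in_lineage else 0
            m_by[sample], cn_by[sample] = m, cn
            if role is SampleRole.NORMAL:
                evaf = 0.5 if origin[v] == "germline" else 0.0
            elif origin[v] == "germline":
                evaf = _germline_tumor_vaf(m, cn, config.purity)
            else:
                evaf = expected_vaf(m, cn, config.purity)
            vaf, depth = _observe(vaf_rng, evaf, config.mean_depth)
            calls[sample].append(VariantCall(v, sample, vaf, depth, SIMULATED_MQ))
        truth.append(TruthRecord(
            variant=v, clone_of_origin=origin[v], haplotype=birth_hap[v],
            is_truncal=origin[v] == "founder", m=m_by, total_cn=cn_by,
            region_label=region_truth[v.contig]))

    segments = {
        sample: [CopyNumberSegment(c, 1, config.contig_length,
                                   len(sample_copies[sample][c]), sample)
                 for c in contigs]
        for sample in roles
    }
    return SimulatedCase(
        config=config, genome=genome, roles=roles, calls=calls, segments=segments,
        truth=truth, region_truth=region_truth, lineage_newick=lineage.newick(),
        private_loh=private_loh, truncal_lost_hap=truncal_lost_hap)


def _germline_tumor_vaf(m: int, cn: int, purity: float) -> float:
    """Germline het VAF in a tumor sample: the admixed normal also carries one alt copy."""
    denom = cn * purity + 2.0 * (1.0 - purity)
    if denom == 0:
        return 0.0
    return (m * purity + (1.0 - purity)) / denom


def _observe(rng: np.random.Generator, evaf: float, mean_depth: int) -> tuple[float, int]:
    if mean_depth <= 0:
        return evaf, NOISE_FREE_DEPTH
    depth = int(rng.poisson(mean_depth))
    if depth == 0:
        return 0.0, 0
    alt = int(rng.binomial(depth, evaf))
    return alt / depth, depth


def _true_region_labels(config: SimulationConfig, roles: dict[str, SampleRole],
                        sample_copies: dict[str, dict[str, list[str]]],
                        ) -> dict[str, RegionLabel]:
    """True per-contig cohort label from the haplotypes surviving in each tumor sample."""
    labels: dict[str, RegionLabel] = {}
    tumors = [s for s, r in roles.items() if r is not SampleRole.NORMAL]
    for contig in config.contigs:
        states = []
        for s in tumors:
            haps = {_hap(cp) for cp in sample_copies[s][contig]}
            states.append(len(haps) == 1)
        if all(states):
            labels[contig] = RegionLabel.TRUNCAL_LOH
        elif any(states):
            labels[contig] = RegionLabel.PRIVATE_LOH
        else:
            labels[contig] = RegionLabel.RETAINED_HET
    return labels


def scaled_config(**overrides) -> SimulationConfig:
    """Convenience constructor used by tests and the acceptance script."""
    return replace(SimulationConfig(), **overrides)
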