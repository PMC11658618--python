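from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pamtrace.discovery import (
    annotate_context,
    gc_fraction,
    scan_novel_pams,
    somatic_subtract,
)
from pamtrace.model import (
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

BASES = "ACGT"


def _register_oracle(germ: str, pos: int, alt: str):
    """Exhaustive string-matching oracle: every register overlapping pos on
    both strands, novel iff mutant matches NGG (plus) / CCN (minus) and the
    germline does not."""
    mut = germ[:pos - 1] + alt + germ[pos:]
    events = []
    for start in range(max(1, pos - 2), min(len(germ) - 2, pos) + 1):
        g = germ[start - 1:start + 2]
        m = mut[start - 1:start + 2]
        if m[1:] == "GG" and g[1:] != "GG":
            events.append(("+", start))
        if m[:2] == "CC" and g[:2] != "CC":
            events.append(("-", start))
    return sorted(events)


def test_scanner_matches_exhaustive_five_mer_oracle():
    """All germline 5-mers x all center substitutions versus the brute-force
    register-matching oracle, with the strand/count invariants checked on
    every produced event."""
    n_checked = 0
    for germ in map("".join, product(BASES, repeat=5)):
        ref = germ[2]
        for alt in BASES:
            if alt == ref:
                continue
            n_checked += 1
            variant = Variant("c", 3, ref, alt)
            events = scan_novel_pams({"c": germ}, variant)
            got = sorted((e.strand.value, e.pam_register) for e in events)
            assert got == _register_oracle(germ, 3, alt), (germ, alt)
            assert len(events) <= 2
            for e in events:
                assert (e.strand is Strand.PLUS) == (alt == "G")
                assert (e.strand is Strand.MINUS) == (alt == "C")
    assert n_checked == 3 * 4 ** 5


def test_canonical_t_to_g_example_creates_plus_strand_pam():
    # germline ATG; T>G at the middle gives AGG, a new NGG register
    events = scan_novel_pams({"c": "ATG"}, Variant("c", 2, "T", "G"))
    assert [(e.strand, e.pam_register) for e in events] == [(Strand.PLUS, 1)]


@pytest.mark.parametrize("alt", ["A", "T"])
def test_a_or_t_substitutions_never_create_pams(alt):
    rng = np.random.default_rng(0)
    for _ in range(50):
        seq = "".join(rng.choice(list(BASES), size=30))
        pos = int(rng.integers(3, 28))
        if seq[pos - 1] == alt:
            continue
        assert scan_novel_pams({"c": seq}, Variant("c", pos, seq[pos - 1], alt)) == []


def test_novel_registers_are_never_pams_in_the_germline():
    """Novelty means the germline does not already match at the same register
    and strand; re-reading each reported register in germline confirms it."""
    rng = np.random.default_rng(1)
    for _ in range(300):
        seq = "".join(rng.choice(list(BASES), size=40))
        pos = int(rng.integers(3, 38))
        ref = seq[pos - 1]
        alt = str(rng.choice([b for b in BASES if b != ref]))
        for e in scan_novel_pams({"c": seq}, Variant("c", pos, ref, alt)):
            germ = seq[e.pam_register - 1:e.pam_register + 2]
            mut = (seq[:pos - 1] + alt + seq[pos:])[e.pam_register - 1:e.pam_register + 2]
            if e.strand is Strand.PLUS:
                assert mut[1:] == "GG" and germ[1:] != "GG"
            else:
                assert mut[:2] == "CC" and germ[:2] != "CC"


def test_strand_symmetry_under_reverse_complement():
    """Mirroring the reference and the variant swaps strands but preserves
    the number of novel registers."""
    rng = np.random.default_rng(2)
    comp = dict(zip("ACGT", "TGCA"))
    for _ in range(200):
        seq = "".join(rng.choice(list(BASES), size=31))
        pos = int(rng.integers(3, 29))
        ref = seq[pos - 1]
        alt = str(rng.choice([b for b in BASES if b != ref]))
        fwd = scan_novel_pams({"c": seq}, Variant("c", pos, ref, alt))
        mirrored = Variant("c", len(seq) - pos + 1, comp[ref], comp[alt])
        rev = scan_novel_pams({"c": revcomp(seq)}, mirrored)
        assert len(fwd) == len(rev)
        assert sorted(e.strand.value for e in fwd) == \
            sorted({"+": "-", "-": "+"}[e.strand.value] for e in rev)


def test_reference_mismatch_is_an_error():
    with pytest.raises(ReferenceMismatchError):
        scan_novel_pams({"c": "AAAA"}, Variant("c", 2, "C", "G"))


def test_contig_edge_registers_skipped_silently():
    # alt G at the last base: the only register needing bases beyond the end
    events = scan_novel_pams({"c": "ATG" + "A"}, Variant("c", 4, "A", "G"))
    assert all(e.pam_register + 2 <= 4 for e in events)


# ---------------------------------------------------------------- subtraction

def _call(contig, pos, ref, alt, sample="T", vaf=0.5, depth=50, mq=60.0):
    return VariantCall(Variant(contig, pos, ref, alt), sample, vaf, depth, mq)


def test_subtraction_is_filtered_set_difference():
    t1, t2 = _call("c", 10, "A", "G"), _call("c", 20, "C", "T")
    n2 = _call("c", 20, "C", "T", sample="N")
    assert somatic_subtract([t1, t2], [n2]) == [t1.variant]


@pytest.mark.parametrize("kwargs,kept", [
    (dict(depth=9), False),        # below depth 10
    (dict(depth=10), True),        # boundary inclusive
    (dict(mq=19.0), False),        # below MQ 20
    (dict(vaf=0.04), False),       # below AF 0.05
    (dict(vaf=0.05), True),
])
def test_tumor_quality_filters(kwargs, kept):
    call = _call("c", 5, "A", "G", **kwargs)
    result = somatic_subtract([call], [])
    assert (result == [call.variant]) is kept


def test_self_subtraction_by_sample_name_is_an_error():
    call = _call("c", 5, "A", "G")
    with pytest.raises(PamTraceError, match="same sample"):
        somatic_subtract([call], [call])


def test_subtracting_matching_normal_set_empties_result():
    tumor = [_call("c", i, "A", "G") for i in range(1, 20)]
    normal = [_call("c", i, "A", "G", sample="N") for i in range(1, 20)]
    assert somatic_subtract(tumor, normal) == []
    assert somatic_subtract(tumor, []) == sorted(c.variant for c in tumor)


def test_zero_support_normal_records_do_not_veto():
    tumor = [_call("c", 5, "A", "G")]
    normal = [_call("c", 5, "A", "G", sample="N", vaf=0.0)]
    assert somatic_subtract(tumor, normal) == [tumor[0].variant]


def test_subtraction_matches_brute_force_oracle():
    rng = np.random.default_rng(3)

    def random_calls(sample, n):
        out = []
        for _ in range(n):
            pos = int(rng.integers(1, 40))
            ref, alt = rng.choice(list(BASES), size=2, replace=False)
            out.append(VariantCall(Variant("c", pos, str(ref), str(alt)), sample,
                                   float(rng.uniform(0, 1)), int(rng.integers(0, 60)),
                                   float(rng.uniform(0, 60))))
        return out

    for _ in range(20):
        tumor, normal = random_calls("T", 50), random_calls("N", 50)
        expect = set()
        for c in tumor:  # naive double loop
            if c.mapping_quality < 20 or c.depth < 10 or c.vaf < 0.05:
                continue
            if any(n.variant == c.variant and n.vaf >= 0.05 for n in normal):
                continue
            expect.add(c.variant)
        assert set(somatic_subtract(tumor, normal)) == expect


# ---------------------------------------------------------------- sgRNA design

def test_saturated_gc_protospacer_is_suboptimal():
    seq = "G" * 20 + "ATG" + "A" * 5
    ev = scan_novel_pams({"c": seq}, Variant("c", 22, "T", "G"))[0]
    assert ev.protospacer == "G" * 20
    assert ev.gc_fraction == 1.0 and ev.gc_optimal is False


def test_gc_window_boundaries_are_inclusive():
    proto = "GCGCGCGC" + "A" * 12  # 8/20 = 0.40
    seq = proto + "ATG" + "T" * 25
    ev = scan_novel_pams({"c": seq}, Variant("c", 22, "T", "G"))[0]
    assert ev.gc_fraction == pytest.approx(0.40)
    assert ev.gc_optimal is True


@settings(derandomize=True, max_examples=50)
@given(st.text(alphabet=BASES, min_size=20, max_size=20))
def test_gc_fraction_equals_direct_count(proto):
    assert gc_fraction(proto) == (proto.count("G") + proto.count("C")) / 20


def test_insufficient_flank_flags_undesignable_without_dropping():
    seq = "ATG" + "A" * 30  # PAM register at 1: no room for a 20-mer 5' of it
    ev = scan_novel_pams({"c": seq}, Variant("c", 2, "T", "G"))[0]
    assert ev.designable is False and ev.protospacer is None


def test_minus_strand_protospacer_is_reverse_complemented():
    rng = np.random.default_rng(4)
    seq = "T" * 10 + "CAN".replace("N", "A") + "".join(rng.choice(list(BASES), size=25))
    # make a C>C-creating SBS: germline 'CA' -> alt C at pos 12 gives 'CC'
    ev_list = scan_novel_pams({"c": seq}, Variant("c", 12, "A", "C"))
    minus = [e for e in ev_list if e.strand is Strand.MINUS]
    assert minus
    ev = minus[0]
    start = ev.pam_register
    assert ev.protospacer == revcomp(seq[start + 2:start + 22])


# ---------------------------------------------------------------- context

def _event(contig, pos):
    return PamEvent(Variant(contig, pos, "A", "G"), Strand.PLUS, pos)


def test_empty_annotation_labels_everything_intergenic():
    assert annotate_context(_event("c", 100), []) is GenomicContext.INTERGENIC


def test_coding_and_near_coding_labels():
    genes = [GeneModel("c", 1000, 5000, "g1", coding=((2000, 3000),))]
    assert annotate_context(_event("c", 2500), genes) is GenomicContext.CODING
    assert annotate_context(_event("c", 1500), genes) is GenomicContext.INTRON_OR_NEAR_CODING
    assert annotate_context(_event("c", 6500), genes) is GenomicContext.INTRON_OR_NEAR_CODING
    assert annotate_context(_event("c", 900000), genes) is GenomicContext.INTERGENIC


def test_context_labels_match_linear_scan_oracle():
    rng = np.random.default_rng(5)
    genes = []
    for i in range(5):
        start = int(rng.integers(1, 80_000))
        end = start + int(rng.integers(500, 5000))
        cs = int(rng.integers(start, end - 100))
        genes.append(GeneModel("c", start, end, f"g{i}",
                               coding=((cs, cs + 100),)))
    near = 2000
    for _ in range(100):
        pos = int(rng.integers(1, 100_000))
        got = annotate_context(_event("c", pos), genes, near_window=near)
        if any(cs <= pos <= ce for g in genes for cs, ce in g.coding):
            expect = GenomicContext.CODING
        elif any(g.start - near <= pos <= g.end + near for g in genes):
            expect = GenomicContext.INTRON_OR_NEAR_CODING
        else:
            expect = GenomicContext.INTERGENIC
        assert got is expect, pos
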