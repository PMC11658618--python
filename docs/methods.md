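# Methods

## The model

A somatic single-base substitution (SBS) creates a *novel PAM* when the
mutant sequence matches the SpCas9 motif NGG at a 3-base register and
strand where the germline sequence does not. Because N matches any base,
novelty requires a newly created GG (plus strand) or CC dinucleotide (minus
strand, whose plus-strand image is CCN): an SBS to G can only create
plus-strand registers, an SBS to C only minus-strand ones, and substitutions
to A or T never create a PAM. At most two registers per SBS can become
novel. `pamtrace` implements novelty as exact register matching (mutant
matches, germline does not, at the same register and strand), which is
directly checkable against a brute-force string-matching oracle and handles
run extensions correctly (GGG → GGGG yields exactly one new register).
NAG off-target PAMs are deliberately out of scope.

The protospacer is the 20 bases immediately 5′ of the PAM on the PAM strand
(reverse-complemented for minus-strand events); the sgRNA efficiency window
is 0.40 ≤ GC ≤ 0.80, inclusive on both ends. Events too close to a contig
end for a full protospacer are flagged undesignable rather than dropped.

### Expected VAF

For a variant carried by `m` of `cn` tumor copies in a sample of tumor
purity `p`, the expected variant allele fraction is

    VAF(m, cn, p) = m·p / (cn·p + 2·(1 − p))

— the admixed normal contributes two reference copies (for germline
heterozygous sites the normal contributes one alternate copy, handled
separately inside the simulator). At `p = 1` this reduces to `m/cn`: 1 in
haploid LOH, 1/2 for diploid heterozygous, 1/3 and 2/3 in triploid regions.
The degenerate denominator (`cn = 0`, `p = 1`) returns 0. This closed form
is what makes LOH legible from sequencing: a truncal variant in a region
reduced to one copy must sit at VAF 1.

### LOH classification

A single PAM observation is called LOH at VAF ≥ 0.95 (threshold inclusive),
HET below it, and uninformative when the PAM is absent from the sample. A
*region* is called LOH in a sample when its copy number is 1 **or** the mean
VAF of its presence-called PAMs reaches the threshold — the disjunction is
what detects copy-neutral LOH at CN 2. Region/sample copy number is the
majority CN over the region's covered PAM positions (so mixed arms are
labeled by their PAM-bearing bases); mean VAF uses presence-called PAMs
only, so absent PAMs cannot deflate the signal. When a truncal PAM set is
available the VAF rule is restricted to truncal PAMs: sample-private
mutations arise *after* an early copy-neutral LOH, sit at VAF 1/2, and
would otherwise mask the uniformly high VAF of the truncal ones.

Across the cohort a region is TRUNCAL_LOH if LOH in every informative tumor
sample, PRIVATE_LOH if LOH in at least one but not all, RETAINED_HET if LOH
in none, and UNINFORMATIVE with fewer than two informative samples.

### Maintenance statistics

Presence of a PAM in a capture sample requires depth ≥ 20 and VAF ≥ 0.05
(just above background artifact noise); cells below the depth floor are
`no_coverage`, never "absent", and are excluded from both numerator and
denominator of any statistic they would enter (the affected cell count is
reported). Truncal PAMs are those present in **any** primary sample and
absent in the matched normal; a case without a primary falls back to
"present in more than one metastasis". Percent truncal (per metastasis),
percent maintained (per PAM), and percent shared-by-all-lesions follow from
the presence matrix by counting; case-level summaries are unweighted means
with SEM. An empty truncal set yields flagged NaN percentages, not silent
zeros. Sample QC is a mean-capture-depth threshold (default 20×) plus a
depth-versus-percent-truncal table for manual review; a low-cellularity
sample with adequate depth is retained but visible in that table.

Group comparisons dispatch to standard routines: Mann-Whitney for two
groups, Kruskal-Wallis for three or more, one-way ANOVA on request
(scipy.stats). When every pooled observation is identical the comparison
returns p = 1 rather than an error.

### Sample trees

Distances are raw Hamming counts between binary presence columns, computed
over sites where neither sample is `no_coverage` (pairwise deletion); a
pair with no comparable sites is an error. UPGMA uses size-weighted average
linkage with node height = merge distance / 2, so the tree is ultrametric
before re-rooting; merge ties are broken lexicographically by concatenated
member names so permuting input order cannot change the topology. The tree
is then re-rooted on the pendant branch (at its midpoint) of the primary
with the fewest *unique* PAMs — present in it and in no other sample —
which is the sample closest to the founder clone; ties are lexicographic
and logged. scipy's average linkage serves as an independent oracle in the
test suite; scikit-bio handles Newick serialization and Robinson-Foulds
comparisons.

## The simulator

The simulator emulates a rapid-autopsy pancreatic-cancer case: a
haplotype-resolved toy genome (i.i.d. bases at a configurable GC content,
default 0.41; two copies per contig, polyploid contigs replicate one
haplotype), germline heterozygous sites carried by haplotype B, a founder
clone with truncal SBS, truncal LOH applied in the founder *before* lineage
branching, and metastases that each draw private whole-contig LOH events
and private SBS. The normal sample is diploid everywhere and carries only
germline variants.

Every somatic SBS is assigned to a single chromosome *copy*, uniformly
among the founder's copies of its contig. This per-copy bookkeeping is the
mechanism behind the loss rules: losing one of two copies loses the variant
with probability 1/2, losing one of three with probability 1/3, and losing
a whole haplotype removes exactly the variants on it while fixing the rest
at VAF 1. Copy-neutral LOH duplicates the retained copy together with the
variants it carries, producing VAF 1 at CN 2. Truncal LOH on polyploid
contigs is rejected at validation so the VAF classes stay unambiguous.

The metastasis lineage is a random bifurcating join tree whose node heights
are the join order. With `n_branch_sbs > 0`, every branch receives shared
SBS proportional to its height span, making the lineage clock-like — the
regime in which UPGMA provably recovers the topology; the default is 0
(metastases differ only by their private events). Emitted VAFs are exact
model values when `mean_depth = 0` (records carry a nominal depth of 1000);
otherwise depth is Poisson and alt reads binomial. Every case variant is
emitted in every sample's VCF, capture-style, including zero-support
records — which is why the somatic subtraction counts a normal record as
evidence only at VAF ≥ 0.05. Randomness derives from one master seed with
per-stage and per-sample substreams (seed + CRC32 of a stage label), so
adding a metastasis does not perturb the others and identical configs give
byte-identical output files.

What the simulator does **not** model — and hence what passing tests do not
show about real data: read-level artifacts (FFPE damage, mapping error,
probe specificity), subclonal structure within a sample beyond a single
purity, indels and structural variants, mutation signatures (alt bases are
uniform over the three non-reference bases), and sub-contig LOH segments
(events are whole-contig). Real capture panels also have uneven coverage;
the simulator's `no_coverage` path is exercised in tests with constructed
matrices instead.

## Defaults and parameters

| parameter | default | units | rationale |
|---|---|---|---|
| tumor filter: MQ / depth / AF | 20 / 10 / 0.05 | phred, reads, fraction | discovery-grade variant filters |
| presence VAF cutoff | 0.05 | fraction | just above capture background noise |
| presence depth floor | 20 | reads | below it a site is `no_coverage` |
| LOH VAF threshold | 0.95 | fraction | high-VAF LOH call, inclusive |
| sgRNA GC window | 0.40–0.80 | fraction | efficient-guide design window, inclusive |
| near-coding window | 2000 | bases | "near coding" is not standardized; fixed here |
| uncovered-PAM CN | 2 | copies | diploid fallback, counted in a warning |
| simulator genome | 10 × 100 kb | contigs × bases | desk-scale stand-in for chromosome arms |
| truncal SBS | 1000 | count | gives ~200 PAM sites at the ~19% conversion rate observed for uniform SBS at GC 0.41 |
| metastases / private LOH | 4 / 2 per met | count | several lesions, LOH in a subset |
| purity / depth | 1.0 / 0 (noise-free) | fraction, reads | cell-line-like setting; noise opt-in |

## Evaluation problem sizes

The acceptance script (`scripts/acceptance.py`) uses the default case for
the truncal-LOH maintenance statistic (~30 truncal PAMs in truncal-LOH
regions; the value is exactly 100 regardless of n) and scales the haploid-
and triploid-loss cases to 15 000 truncal SBS so that > 2000 truncal PAMs
pool onto the affected contigs, putting three binomial standard deviations
at about ±3 percentage points around the expected 50% and 33.3% loss
fractions. Affected regions are identified from pipeline outputs (region
labels and emitted segment CN), not from simulator ground truth; the truth
tables serve as independent oracles in the test suite only.

## Known limitations

- Region granularity is whatever interval map is supplied (whole contigs by
  default); sub-segment LOH inside a supplied region is aggregated by
  majority of PAM-bearing sites, which can mislabel a region whose PAMs
  split evenly across states.
- The truncal definition is operational (presence in any primary), not
  phylogenetic; early-subclone PAMs present in one primary section are
  counted truncal.
- `somatic_subtract` treats any normal-sample allele support ≥ 5% as
  germline evidence; very low-level tumor-in-normal contamination would
  delete true somatic PAMs.
- UPGMA assumes clock-like divergence; on strongly rate-heterogeneous
  lineages the tree is a clustering, not a phylogeny.
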