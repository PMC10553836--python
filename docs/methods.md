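# Methods

This note documents the models, estimators and numerical choices behind the
package, what the synthetic-data generator does and does not emulate, and
the design decisions taken where the methodology was genuinely open.

## Allelic phenotypes and harmonization

Microsatellite dosage cannot be read from fragment traces in polyploids, so
all analyses operate on *allelic phenotypes*: per sample and locus, the set
of distinct fragment lengths (bp). The native table format is tab-separated
text with one comma-separated ascending allele list per locus cell; an empty
cell is a missing locus. Reading and writing are mutually inverse on valid
data, and the writer emits a canonical row/column order so outputs are
byte-stable.

Fragment lengths scored in different laboratories can carry a small constant
per-locus offset (different sizing ladders and machines). The harmonizer
assumes a linear shift and estimates it by aligning the *modal* fragment
length of the source dataset to that of the reference, where each sample
contributes each of its distinct alleles once. Ties among modes generate
candidate shifts; the smallest |shift| wins, then the negative one. A
required shift beyond ±3 bp is treated as evidence against a simple
laboratory offset and raises instead of silently adjusting. Because the
shift is a translation of all alleles at one (dataset, locus), within-dataset
Bruvo distances are invariant under harmonization (tested).

## Ploidy and multilocus genotypes

Measured ploidy (e.g. flow cytometry), when present in the metadata, is used
as-is. Otherwise ploidy is estimated as the maximum number of distinct
alleles over loci; for samples of section *Caninae* one is added, because
members of this section typically carry at least one allele in two copies
(the near-homozygous bivalent pair), so apparent counts understate ploidy by
about one. The estimate is floored at 2. This estimator can only
*understate* true ploidy (null alleles, shared lengths), which is why the
package never asserts estimated ≤ measured.

Samples with identical phenotypes at every locus receive the same MLG index.
Missing loci are a distinct token: profiles match only when their missing
patterns are identical, so samples are never conflated on absent evidence.
Two indices are kept, following the two analyses they serve: a global index
(identical phenotypes match across sites and species — used for per-site
clonal richness and shared-MLG geography) and a per-(site, species) index
(used for per-species diversity, where a repeated phenotype in a different
unit counts as a distinct genotype).

Clonal richness is R = (G−1)/(N−1); it is reported as missing for N = 1
(0/0 in the formula) rather than 1.0. Shannon H uses natural logarithms over
MLG frequencies and evenness is Pielou's E = H/ln G (undefined for G = 1) —
the standard clonal-diversity convention. Distances between samples sharing
an MLG use the haversine formula on a sphere of mean radius 6371.0 km;
kilometre-scale precision is ample for the >1000 km patterns of interest.

## Bruvo distances

Per allele pair, dₐ = 1 − 2^(−|Δ|/motif): zero for identical lengths,
saturating towards 1 with the number of repeat units separating them. Motif
lengths are configurable per locus and default to 2 bp for all seven panel
loci (the panel derives from dinucleotide-repeat-rich markers; a uniform
default keeps results internally consistent and is surfaced prominently in
`LocusPanel`).

Equal-size allele sets are compared by the minimum over bijections of the
mean per-pair distance. This is an assignment problem, solved exactly with
the Hungarian algorithm; a brute-force search over permutations serves as
the independent oracle in tests. Unequal sizes are first brought to the
larger set's size by one of two dosage-agnostic strategies:

- `mean_completion` (default): the smaller phenotype is completed with
  multisets of its own alleles, and the exact-matching distance is averaged
  over all completions — the averaging treatment of unknown dosage
  introduced with the distance itself;
- `virtual_allele`: the smaller set is padded with a virtual allele at
  distance 1 to everything (a conservative upper-bound treatment).

Both strategies coincide when the sets already have equal size, and
identical phenotypes are always at distance zero. Sample distance is the
unweighted mean over loci non-missing in both samples; samples sharing no
scored locus are an error, not a zero.

For ordination and AMOVA the sampling unit is one copy of each MLG per
species (flag-controlled), so clonal amplification does not weight the
variance decomposition.

## PCoA

Classical scaling: double-centre −D²/2, eigendecompose, keep the
positive-eigenvalue axes (relative tolerance 1e−10 on the leading
eigenvalue), scale eigenvectors by √λ. Percent variance is relative to the
positive-eigenvalue total and axis signs are fixed so the largest-magnitude
loading on each axis is positive, making outputs deterministic. The
implementation is cross-checked against scikit-bio's PCoA in the test suite
and recovers Euclidean configurations to 1e−9.

## AMOVA

One-level distance-based AMOVA from the squared-pairwise-distance identity
SS_total = Σ_{i<j} d²ᵢⱼ/n, with the within-group analogue per group; raw
Bruvo distances are squared by default (`squared=False` feeds them in as
already squared — the conventions differ between software packages, so the
switch is exposed). Degrees of freedom are G−1 among and N−G within;
variance components use the average-group-size coefficient
n₀ = (N − Σn_g²/N)/(G−1), and Φst = σ²_among/(σ²_among + σ²_within).

A negative among-group component is clamped to 0 in the *reported*
components (standard practice for method-of-moments estimators), but the
permutation test compares the *unclamped* statistic: clamping inside the
comparison would pile permutation mass at the observed value and bias the
p-value towards 1 under the null. With the unclamped statistic the
permutation p-value is approximately uniform under random labels (tested
with a Kolmogorov–Smirnov check over 200 replicates). The p-value is
(1 + #{permuted Φ ≥ observed})/(n_perm + 1) with 999 permutations by
default and an explicit seed.

## Most frequent allele combinations (MFAC)

Analysis groups are subsection × estimated-ploidy class:
Caninae 5x, Rubigineae 5x, Vestitae 5x and Vestitae 4x (only the
morphologically heterogeneous Vestitae are split by ploidy). Samples
estimated hexaploid or higher are excluded, as such profiles frequently
reflect inter-subsection hybrids. With the seven panel loci this yields the
28 locus×group analysis cells. Optional de-duplication of repeat MLGs
within (species, site) is available (off by default) to check robustness to
local clonal amplification.

A sample *carries* a size-k combination S iff its phenotype contains S
(containment, not exact identity — the nesting logic of co-inherited sets
requires subset counts to dominate, which containment guarantees; an
`exact_match` switch exists for sensitivity analysis). Combinations are
ranked by carrier count, ties by lexicographic allele order, and the top ten
per k ∈ {2, 3, 4} are retained.

**Frequency test.** The null model draws m = ploidy alleles iid from the
relative allele frequencies of the locus×group — the carrier probability of
S at Hardy–Weinberg equilibrium under fully sexual polysomic inheritance,
with duplicate draws modelling hidden same-length alleles. By
inclusion–exclusion,
p₀ = Σ_{T⊆S} (−1)^|T| (1 − Σ_{a∈T} p_a)^m,
and the test is the upper binomial tail P(X ≥ carriers | n, p₀). The
closed form is verified exactly against exhaustive enumeration, and the
test's empirical type-I error under its own null sits at the nominal level
(the check uses 1000 samples per replicate so the discrete binomial tail is
fine-grained near α).

**Specificity test.** Whether the MFAC is over-represented in its group
relative to the pooled data is tested with the upper hypergeometric tail:
N pooled samples, K pooled carriers, n focal samples, x focal carriers.
Group sizes enter through n and N, which realizes the sample-size weighting
of the comparison. The pool includes the focal group by default (a switch
excludes it). No multiple-testing correction is applied by default; optional
Bonferroni across the 28 cells sits behind a flag. Significance marks:
stars at 0.05/0.01/0.001 for the binomial test, a degree sign for
specificity at a configurable threshold (default 0.01).

**Networks.** Up to ten equal-k combinations are laid out counter-clockwise
from the top in decreasing frequency; edges join combinations sharing k−1
alleles (one allele exchanged, deliberately with no stepwise-mutation
assumption); node size is frequency relative to the MFAC, and the plot is
flagged faded when f(MFAC) < 0.2. Exports: GraphML, DOT, matplotlib.

**Categories.** The visual classification of locus×group patterns is
formalised as an ordered rule set (first hit wins), with every decision
logged with the rule that fired:

1. **BC₁** — ≥2 near-equal top combinations (within 10% relative frequency)
   at the candidate size k = ploidy−1, each below the 0.2 fade threshold;
2. **BC₂** — nesting inconsistency: the top k-set is not a subset of the top
   (k+1)-set;
3. **A** — the top (ploidy−1)-set has f ≥ 0.2 and binomial p ≤ 0.001;
4. **B** — a smaller top set (largest k first) has f ≥ 0.2 and p ≤ 0.001;
5. **C** — otherwise (including the "most samples show ploidy−1 alleles but
   no such set is frequent" case, cf(ploidy−1) ≥ 0.5).

All thresholds are configurable (`Thresholds`); the defaults above are the
package's documented operating point.

## The canina-meiosis simulator

Each lineage plants, per locus, u = m − 2 fixed univalent alleles and a
bivalent allele pool with one allele near fixation (default frequency 0.9,
two minor variants). The default study conditions emulate a scaled-down
multi-site survey of the four analysis groups: four lineages with disjoint
planted univalent sets but a shared bivalent pool (mirroring alleles common
to all subsections), six random European sites, 25 final samples per lineage
and site (600 total), five founders per deme, ten non-overlapping
generations, stepwise mutation at 10⁻³ per allele per transmission for both
univalent and bivalent genomes, 1% phenotype-level null-allele dropout per
genome copy, 10% vegetative clonality, 10% selfing, and measured ploidy
available for ~36% of samples (roughly the share of flow-cytometry ploidy
in the emulated survey design). No empirical mutation or null rates exist
for these loci; the defaults are documented operating points for
sensitivity analysis, not estimates.

Transmission per sexual offspring: the mother's u univalent genomes
(mutated at μ_u), one maternal and one paternal bivalent allele (father
drawn within site and lineage, or the mother with the selfing probability;
mutated at μ_b). A clonal offspring copies the whole genotype unchanged.
Stepwise mutation moves ±1 motif unit with equal sign probability (±2 steps
behind a flag). Null alleles are phenotype-level dropouts per genome copy,
not heritable primer mutations (the simplest model producing the observed
set shrinkage); apomixis is not distinguished from vegetative cloning —
both are exact clones. Allele sizes sit on a per-locus motif lattice so
mutation keeps them in register. Everything is reproducible from one seed.

**Truth recovery** groups samples by their *true* lineage from the truth
tables and asks, per locus×lineage, whether the detected MFAC contains (or
equals) the planted univalent set. Grouping by truth rather than by
estimated ploidy is deliberate: at bivalent near-fixation 0.9, ~18% of
samples per locus show a heterozygous bivalent, so allele-count ploidy
estimation shifts an appreciable share of samples one class up; recovery is
meant to measure the MFAC detector given correct lineage assignment, while
the estimated-ploidy grouping path is exercised by the pipeline itself and
its tests. Without mutation and nulls, containment of the planted set is
exactly 1 and all 28 cells classify as category A (planted set plus the
dominant bivalent allele); recovery degrades monotonically with μ_u and the
planted sets are strongly group-specific (hypergeometric p ≤ 10⁻³ at ≥50
samples per lineage).

## What the simulator does not emulate

Real surveys add: uneven and spatially clustered sampling, inter-subsection
hybridisation (the main source of apparent hexaploids), between-site gene
flow, allele-length homoplasy across lineages, heritable null alleles,
linkage between loci sharing a chromosome (the panel's two linked pairs are
simulated as free), selection, and misidentified species. Passing tests on
simulated data therefore demonstrate the *correctness of the estimators
under the stated model*, not robustness to every field complication; the
pipeline's behaviour under several of these violations (null-allele
inflation, clonal amplification, mutation-rate stress) is probed explicitly
in the test suite.

## Problem sizes and numerical notes

Default test and validation runs use 240–800 simulated samples; the
truth-recovery stress check uses 200 samples per lineage over 20 seeds, and
the pipeline demonstration 600 samples with 999 AMOVA permutations — sizes
chosen so the full validation cycle completes in minutes while every
statistic is comfortably in its asymptotic regime. Locus-level Bruvo
distances are memoised on the (phenotype, phenotype, motif, strategy) key,
which collapses the cost of distance matrices over datasets with repeated
phenotypes. Degenerate inputs fail loudly: empty allele sets, single-group
AMOVA, all-missing samples, and inconsistent test counts all raise typed
errors rather than returning defaults.
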