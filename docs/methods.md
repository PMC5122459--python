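# Methods

This note documents the statistical procedures, the synthetic-data model the
package is validated against, the numerical choices, and the limits of what
the tests demonstrate.

## Burden-association model

The central question is whether the non-silent mutation status of a gene
shifts the distribution of per-sample CNA burden. Burden is summarised per
sample after segment filtering: a segment is retained when its magnitude
|log₂(CN) − 1| strictly exceeds 0.1 and its length (end − start in the
internal 0-based half-open system) is at least 100 bp. `n_cna` is the count
of retained segments and `mean_cna_length` their arithmetic mean (undefined
when `n_cna` = 0; such samples are excluded from length comparisons).

The two-group comparison is a two-sided Mann–Whitney–Wilcoxon test. For
group sizes ≤ 8 the p-value is computed by exact enumeration of all
C(n₁+n₂, n₁) group labelings on mid-ranks, which is exact in the presence of
ties; larger groups use the tie-corrected normal approximation with
continuity correction (scipy). The effect size is
log₂((μ_mut + 1)/(μ_non + 1)); the pseudocount of 1 guards groups whose mean
burden is zero and is configurable. "Fewer" direction means the mutated
group's mean is below the non-mutated group's.

### Pipelines and their controls

*Pan-cancer*: genes need ≥ 60 non-silent mutations overall; only cancer
types with ≥ 200 samples and, per gene, ≥ 5 mutated samples are pooled.
BH-FDR across the tested genes; candidates need q < 0.01 and |effect| > 0.5.
Two controls follow. The **silent control** repeats the test with groups
defined by silent (synonymous) mutations and removes candidates significant
under the same thresholds — this catches genes whose mutation placement
merely tracks local mutation rate or gene length (long-gene/olfactory-type
confounders), since such placement affects silent and non-silent mutations
alike. The **regression control** fits, per gene and cancer type, an OLS of
CNA number on mutation status and per-sample mutation count, t-tests the
status coefficient, BH-corrects across the fits of *all* tested genes (the
family is the run, not the candidate list — correcting only across a few
extreme candidates would let marginal fits ride on their ranks), and keeps
genes with ≥ 1 type at q < 0.1. Non-silent classes are missense, nonsense,
frameshift and other-non-silent; silent is synonymous only.

*Cancer-type-specific*: hypermutators (mutation count > type median + 2
standard deviations; sample sd, n−1 denominator, configurable) are removed,
the MWW runs per cancer type with ≥ 5 mutated samples, and inference is at
the gene level: a gene's p-value is the Bonferroni bound over its per-type
tests and BH runs across the tested genes. This matches reporting
discoveries as genes and keeps the false-discovery residue of the run at
~q·(#true genes) rather than ~q·(#true gene×type pairs). The silent control
is applied per significant gene in its driving (minimum-p) type.

*Permutation*: the binary gene × sample non-silent incidence matrix is
permuted preserving both margins — each gene keeps its number of mutated
samples, each sample its number of mutated genes — so per-sample mutation
load is controlled by construction. Sampling uses the curveball algorithm
(random pair trades of the symmetric difference of two rows), run per cancer
type; burn-in is ≥ 5 sweeps and recorded draws are separated by ≥ 1 sweep
(≥ 16 trades on very small matrices), where a sweep is one trade per row.
The chain is implemented as a numba kernel over padded sorted index arrays;
margins are conserved exactly by construction and the sampler's uniformity
over the margin-fixed ensemble is verified against exhaustive enumeration in
the tests. The statistic is |Δ mean CNA number| over the pooled samples of
the gene's included types (≥ 5 non-silent mutations per type). The empirical
p-value is by default the plain fraction of permutations reaching the
observed statistic — it can be exactly 0, which is what lets BH-corrected
q-values reach 0.01 at moderate permutation counts; the conservative
add-one estimate ((1+k)/(1+n), strictly positive, super-uniform under the
null) is available via `add_one=True`. The permutation count trades
granularity against runtime: at n_perm = N the smallest non-zero p is 1/N,
and the probability that a burden-neutral gene ties the permutation maximum
(and so receives p = 0) is ≈ 1/(N+1) per gene; recovery runs in the
acceptance suite use N = 5000 so that the expected number of such artifacts
across 500 neutral genes stays near 0.1.

*CNA-length association* runs the same MWW on per-sample mean CNA length
without the effect-size or silent filters, and quantifies the overlap
between length- and number-associated gene sets with a 2×2 Pearson
chi-square over the tested universe.

*Mutation-class contrast* compares CNA numbers between carriers of two
user-defined mutation classes of one gene (e.g. in-domain missense vs
N-terminal truncating); a sample carrying both classes is assigned to class
A, the anticipated stronger-impact class.

## Network randomization

Connectivity of a gene set is its number of internal interactions
(self-interactions excluded) and the size of the largest connected component
of the induced subgraph. The null preserves the degree structure: each
member is replaced by a node of identical degree, and when fewer than 15
candidates share the exact degree the margin widens symmetrically (±1, ±2,
…) until the pool holds ≥ 15; the member is excluded from its own pool and a
node is used at most once within a random set (preventing degenerate
double-counting; a slot falls back to allowing reuse only if its pool is
exhausted). Empirical p-values are add-one corrected, so the floor with
1,000 random sets is 1/1001 ≈ 0.001. The hub-robustness variant drops set
members above a degree cutoff (default 500) and reruns the test.

## Impact scores and VAF

The impact test replaces each target gene by a random gene with *exactly*
the same missense-mutation count (≥ 25 exact-count peers required, otherwise
the target is dropped with a warning) and compares the observed mean
per-mutation score against the replacement null, one-sided (higher =
more damaging), add-one corrected. The statistic is a mean over mutations,
not over genes, so frequently mutated targets weigh more. VAF is alt /
(alt + ref) per mutation; zero-coverage mutations are dropped with a count.
Group comparisons run per cancer type that contributes ≥ 100 group-A
mutations among genes with ≥ 15 non-silent mutations. The category
enrichment is a 2×2 Pearson chi-square without Yates correction (intended
for large expected counts).

## Breakpoints and chromatin context

Recurrent CNA regions with recurrence q < 0.1 contribute both boundary
positions ("region limits"). Breakpoints are deduplicated by exact
(chromosome, position) with tissue-association sets unioned; positions
inside centromere/telomere gaps (half-open membership) and breakpoints
associated with > 3 tissues are excluded. State assignment uses half-open
point membership in the genome-covering 18-state track. The enrichment ratio
for a state is its share among associated (breakpoint, tissue) pairs divided
by its share among non-associated pairs; each state gets a 2×2 chi-square,
and states with fewer than 100 non-associated observations are flagged
unreported (the threshold is a parameter; synthetic panels use smaller
counts). Window sweeps compute the fraction of a window around each
breakpoint covered by merged peak intervals — always over the
chromosome-clipped window length — with one observation per (breakpoint,
tissue) pair, two-sided MWW per window size and Bonferroni across window
sizes. A breakpoint is H3K9me3-enriched when any of its associated tissues
has ≥ 1 peak within the 10 kb window; length comparisons use one
observation per (breakpoint, source region), since a deduplicated breakpoint
may bound several regions. Positional controls compare
distance-to-nearest-chromosome-end between the groups and re-test after
excluding breakpoints within 1 Mb and 10 Mb of the ends.

## Heterochromatin fraction and correlations

A tissue's heterochromatin fraction is the genome share labelled "13_Het" in
its (complete, validated) segmentation. Expression screens compute Pearson r
of each gene's expression with the fraction across tissues (expression units
are taken as given; no normalisation is applied) and compare |r| between a
gene set and its complement by MWW. Burden correlations use Spearman's rho
with p-values per Algorithm AS 89: exact enumeration of the rank statistic S
for n ≤ 9, the Edgeworth series for n ≥ 10 (with the S + 2 lower-tail
continuity shift R's `cor.test` applies), and a t-approximation when ranks
are tied. The Edgeworth series was validated coefficient-for-coefficient
against R 4.3.3 (agreement ~1e-11 where R uses the series); being an
asymptotic expansion it degrades in the far tail at very small n, which is
why the exact branch is the n ≤ 9 default and the series is additionally
cross-checked against enumeration (within 10% in moderate-tail fixtures) in
the tests. Burden means default to post-exclusion (hypermutators, aneuploid)
samples. The reference-epigenome combination test compares the rho
distribution over all admissible cancer-type → tissue assignments (uniform
subsample above 10,000 combinations) against uniformly random assignments by
two-sided MWW.

## Survival

Within one cancer type, after hypermutator and aneuploidy exclusion (the
exclusions precede the quartile cuts), patients are cut at the stratifier's
quartiles; ties at a cut point go to the lower group (bottom = value ≤ Q1,
top = value > Q3). The bottom/top comparison is the log-rank test
(chi-square distributed, 1 df; lifelines); a literal chi-square on
end-of-follow-up event counts is available behind `test="chi2_events"`.
Kaplan–Meier curves are product-limit estimates with right censoring.

## Synthetic-data model

Each generator draws from its own RNG stream derived stably from
`SimConfig.seed`, so identical seed + config gives byte-identical output and
adding a generator never perturbs the others.

**Cohort.** The default study conditions are 4 cancer types × 300 samples
and 505 genes, 5 of them planted modifiers with multiplicative effect 0.3.
Per-sample expected mutation counts are uniform on (20, 80) — chosen so that
genes clear the ≥ 60-mutation inclusion filter at this cohort size — with a
2% hypermutator tail at 5× rate; mutation classes follow a fixed mixture
(55% missense, 25% silent, 7% nonsense, 7% frameshift, 6% other). Planted
modifiers are guaranteed ≥ 5 carriers per type. CNA counts are negative
binomial (dispersion parameter 10 — real CNA counts are overdispersed; the
value is a package default, not an empirical claim) with mean
46 × 0.3^(#mutated planted modifiers) × (tissue het fraction / mean het
fraction); the baseline of 46 CNAs per sample matches the average burden the
analyses are aimed at. Segment lengths are log-normal (median ~1 Mb,
σ = 1), multiplied by `h3k9me3_length_factor` when the segment start lies
within 10 kb of a planted H3K9me3 peak of the sample's tissue. Segment
magnitudes are drawn to pass the filters, plus ~5% deliberately
sub-threshold segments so the filters are exercised; ploidy is ~N(2, 0.2)
with a 5% aneuploid (3–4.2) fraction. Survival times are exponential with
the hazard rising geometrically across within-type CNA-count quartiles (top
vs bottom ratio 3 by default) and independent censoring at 3,000 days.

**Epigenomes.** The model genome is 4 × 50 Mb; chromatin states are assigned
in 100 kb bins, with the number of Het bins set to realise the drawn
heterochromatin fraction (uniform on (0.05, 0.35), spanning the range seen
across real tissues) to within one bin, the other 17 labels random with the
full alphabet guaranteed, and H3K9me3 peaks placed inside Het bins.

**PPI graph.** Barabási–Albert topology (heavy-tailed degrees); the planted
module receives a random spanning path plus internal edges at probability
0.3, guaranteeing a connected induced subgraph.

**Breakpoint panel.** Recurrent regions (~40 per cancer type, log-normal
lengths ~2 Mb median, 80% below the q cutoff) with planted knobs: the
probability that the bin under a breakpoint is forced to Het in associated
vs non-associated tissues (the state-enrichment signal), the probability a
region start receives a nearby H3K9me3 peak (in which case its length is
multiplied by the configured factor), and a few regions shared by four types
to exercise the tissue-count exclusion.

**What the generator does not emulate:** real chromosome structure and
SNP-array noise, subclonal mutation structure, correlated gene panels,
driver selection, or realistic linkage between mutation rate and burden
beyond the planted couplings. Passing recovery tests therefore demonstrates
that the pipelines detect the modelled effect classes at realistic sizes and
control false positives under the modelled nulls — not that real-data
confounders beyond those modelled (e.g. purity, copy-number calling
artefacts) are handled.

## Problem sizes used in the acceptance suite

Oracle checks run on ≤ 8-per-group samples, 100 kb interval fixtures and
≤ 30-node graphs; permutation exactness uses a 4 × 6 matrix against its
fully enumerated ensemble at 10,000 draws; null calibration uses 20 cohorts
of 2 types × 200 samples × 150 genes; planted recovery uses the full default
conditions over 10 seeds (permutation count 5,000); survival power uses 20
cohorts of 240 patients. These sizes give each check stable Monte-Carlo
margins while keeping the suite fast.

## Known limitations

* The fraction-of-permutations p-value can be exactly 0; reported q-values
  of 0 mean "below 1/n_perm", not literal impossibility.
* The Edgeworth branch of AS 89 is unreliable in the extreme tail for
  n < 10 (use the exact branch, which is the default there).
* Degree-matched sampling allows pool reuse for a slot only when the
  no-reuse constraint empties its pool; in pathological graphs (many
  same-degree members, tiny pools) this slightly relaxes the no-collision
  rule.
* The regression control is OLS on counts; a negative-binomial GLM would be
  more faithful to the count nature of the response but is not the default
  (the linear fit matches standard practice for this control).
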