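# Methods

## The model and the procedure

The data are gene-level RNA-seq counts over a 4-donor × 2 cell type
(M1/M2 macrophages) × 3 treatment (NT, IFN-λ3, IFN-λ4) grid. Counts for
gene *g* in sample *s* are modeled as negative binomial with mean
μ<sub>gs</sub> and variance μ<sub>gs</sub> + φμ<sub>gs</sub>², a single
common dispersion φ per analysis. Three contrasts per cell type —
λ3 vs. NT (A), λ4 vs. NT (B), λ4 vs. λ3 (C) — are tested gene by gene;
the DEG rule is |fold change| strictly greater than 1.5 and raw
p < 0.05 (the FDR is reported alongside but does not gate DEG calls).
Signed fold changes use the display convention of the field's top
tables: the ratio when ≥ 1, otherwise the negative reciprocal.

### Normalization

TMM scale factors: the reference sample is the one whose upper-quartile
CPM is closest to the mean upper quartile. For every other sample, genes
zero in either member of the pair are dropped, per-gene log2 ratios M
and average abundances A are formed from count proportions, and the
factor is 2 to the weighted mean of M after double trimming (30% of each
M tail, 5% of each A tail) with inverse asymptotic-variance weights.
Factors are rescaled to geometric mean 1; effective library size =
raw library size × factor. A development-time cross-check against the
reference R implementation on a toy matrix agreed to ~0.2%; exact parity
is not a goal (no tagwise shrinkage, no GLM path).

### Testing

Each gene's counts are equalized to the geometric-mean effective library
size and summed per group. Conditional on the total t, the probability
of group A's sum is f_A(k)·f_B(t−k)/Σ<sub>j</sub>f_A(j)f_B(t−j), where
f_A is the NB pmf with mean n_A·t/(n_A+n_B) and size n_A/φ (a sum of n_A
iid NB variables). The two-sided p sums the probabilities of all splits
no more likely than the observed one, which reduces to the exact
binomial split test at φ = 0. For totals ≤ 2000 the full range is
enumerated; above that, a window covering all probability mass beyond
1e−15 per tail (always including the observed split) is used and the
conditional distribution renormalized — the truncation error is orders
of magnitude below the test's 1e−10 verification tolerance.

The common dispersion is a pooled method-of-moments ratio estimator on
library-equalized counts: φ̂ = Σ(v−m)/Σ(m²−v/n) over genes with
within-group mean m > 1, variance v, n replicates, floored at 0. The
denominator correction removes the upward bias of m² as an estimate of
the squared true mean.

Fold changes are ratios of group-mean CPM (effective library sizes) with
a pseudo-count of 0.5 on each side, which bounds log fold changes for
zero-count groups. A low-expression filter (CPM > 1 in ≥ 2 samples,
configurable) is applied per cell type so the three contrasts of a
triplet share one gene universe and one ordering.

### Classification

Each interferon's effect on a gene is graded: **strong** (significant
vs. NT and |FC| ≥ 4), **moderate** (significant, |FC| < 4), **weak**
(not significant but |FC| ≥ 1.1 *or* significant in contrast C),
**null** otherwise. Direction is the sign of the fold change vs. NT and
is 0 exactly for null tiers. The perturbation verdict for interferon X
given the other interferon Y: strong/moderate ⇒ perturbed; null ⇒
unperturbed; weak ⇒ perturbed only if Y is moderate in the same
direction or weak in the opposite direction (a weak effect under a
strong partner, under a moderate-opposite partner, beside a weak-same
partner, or alone, is unperturbed). The table is symmetric in the two
interferons. Categories: reciprocal (both perturbed, opposite),
same_direction, λ4-unique, λ3-unique, unperturbed-both.

Two deliberate definitional points:

* The **summary counts** (reciprocal, unperturbed-by totals, weak-λ4
  same-direction) are restricted to genes significant in ≥ 1 contrast —
  the membership of the Venn diagrams the headline numbers describe.
  Without this, all-noise weak-weak-opposite pairs (never significant
  anywhere) would inflate the reciprocal tally. Per-gene categories
  still partition *all* classified genes.
* `lambda4_unique_total` is significance-based (significant in B, not
  in A): the published arithmetic (126 + 103 + 10 + 3 = 242) includes
  genes whose weak λ3 effect is perturbation-wise "perturbed", so a
  category-based total would undercount. The perturbation-based unique
  category is reported separately.

The weak-vs-weak same-direction case, which the original decision
schematic does not draw, is classified unperturbed-both.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| fc_thresh | 1.5 | DEG fold-change bound (strict) |
| p_thresh | 0.05 | DEG raw-p bound |
| strong_fc | 4.0 | strong/moderate tier boundary (|FC|) |
| weak_floor_fc | 1.1 | minimum |FC| for a sub-significant weak effect |
| dispersion φ | 0.1 (sim) | NB dispersion, variance μ + φμ² |
| min_cpm / min_samples | 1 / 2 | expression filter |
| ora FDR | 0.05 | BH significance for enrichment provenance labels |

The tier boundaries 4.0 and 1.1 are this package's quantitative choices
for qualitative tiers that were never given numeric ranges; both are
exposed in every interface.

## The synthetic generator

`simdata.simulate_counts` draws the full study grid: per-gene baseline
log2 CPM uniform on (3, 10) (mid-expression genes where the exact test
is well resolved), library sizes log-uniform on (0.5, 2) million so TMM
has real work to do, NB noise at φ = 0.1, and a per-gene N(0, 0.5) log2
offset between M2 and M1 baselines (polarization reshapes the
transcriptome, which is what separates cell types in a PCA). Planted
archetypes (70% null by default) assign each gene λ3/λ4 log2 effects
from tiers strong = 2, moderate = 1, weak = 0.45; λ4 effects in M2 are
multiplied by 0.25, emulating the higher signalling threshold IFN-λ4
shows in M2 cells — consequently planted-effect recovery is evaluated in
M1, where planted magnitudes are unattenuated. What the generator does
*not* emulate: donor-specific biological covariance, batch effects,
gene–gene correlation, length bias, and tagwise dispersion; passing
recovery tests therefore demonstrates the pipeline's correctness under
its own model, not robustness to all features of real data.

`simdata.build_fixture` is the deterministic counterpart: rows are
*constructed* (tier-band-midpoint fold changes — 8, √6 ≈ 2.449,
√1.65 ≈ 1.285, 1 — and fixed p-values 1e−4/0.5) to land in requested
Venn regions with requested tiers and directions, so fixture tests
exercise the classification algebra alone. The canonical fixture
(`reference_region_counts`) encodes the study's printed region counts;
the two both-significant reciprocal blocks (9 in M1, 1 in M2) are placed
in the triple-overlap region, the natural location for genes whose
vs-NT effects point apart (the arithmetic is identical if they are
placed in A∩B).

## Numerical and design choices

* Exact-test two-sidedness uses the minimum-likelihood rule (sum of all
  outcome probabilities ≤ observed, with a 1+1e−7 tolerance factor for
  ties), matching the exact binomial test convention.
* PCA (top 500 most-variable genes on log2(CPM+1), configurable) fixes
  each component's sign so its largest-magnitude loading is positive,
  making coordinates deterministic across runs and BLAS builds.
* Heat-map orderings use average-linkage Euclidean clustering on
  z-scored log-CPM; zero-variance rows z-score to 0.
* Top tables rank DEGs by |signed FC| descending within direction, ties
  broken by p then gene id.
* ORA restricts each gene set to the analysis universe (all genes
  passing the expression filter), BH-adjusts across tested sets, and
  orders by p with the set name as tiebreak.
* All pipeline outputs are deterministic functions of config + seed;
  nothing timestamps or reorders nondeterministically.

## Problem sizes used in validation

Statistical checks run at the study's natural scale: 2000 genes, 4
donors per group. The null false-positive rate is averaged over 5 seeds;
dispersion recovery uses one 2000-gene draw at φ = 0.2; planted-effect
recall averages 3 seeds. These sizes give Monte-Carlo standard errors
well inside the asserted bands (e.g. ±0.005 on the type-I rate).

## Known limitations

* The exact test assumes the common dispersion is known; it is plugged
  in from the method-of-moments estimate, whose error is negligible at
  2000 genes but not at tens of genes.
* Library-size equalization by scaling-and-rounding group sums is an
  approximation; genes with totals of only a few counts inherit its
  granularity (they are largely removed by the expression filter).
* Classification operates on point estimates of fold changes; tier
  boundaries are hard cuts, so genes near |FC| = 4 jitter between
  strong and moderate (both perturbed, so category calls are stable).
* Only a common dispersion is supported — no tagwise or trended
  estimation, no GLM/quasi-likelihood testing.
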