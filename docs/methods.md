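# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Two-sample MR model

The estimand is θ, the effect of a one-SD change in a gene's expression
in one immune cell type on the outcome trait. Instruments are cis-eQTL
variants; under the usual instrumental-variable assumptions (relevance,
independence, exclusion restriction) the per-variant ratio
β_out,j/β_exp,j estimates θ.

**Instrument selection.** Three sequential filters per gene × cell type:
cis-eQTL significance p < 5×10⁻⁵; greedy LD clumping at r² ≤ 0.001
(ascending p, ties broken by variant id; a variant is kept iff its squared
correlation with every already-kept variant is at or below the cutoff);
and instrument strength F = (β/se)² ≥ 10 (the boundary value 10 is kept —
the exclusion rule is "below 10"). An r²-based F, (n−2)r²/(1−r²), is
available as `f_statistic_from_r2`. Note that greedy clumping is not
monotone in the cutoff: loosening r² can admit an early variant that
blocks several later ones, shrinking the retained set; this is a property
of the standard algorithm, not a defect. LD comes from a user-supplied
per-locus correlation matrix (the generator provides one); the package
never computes LD from genotypes.

**Harmonization.** Outcome effects are aligned to the exposure effect
allele: matching allele pairs pass, swapped pairs negate β and reflect
the allele frequency, anything else is dropped as a mismatch. Both
datasets are assumed on the same strand — no complement rescue — so A/G
vs C/T at one id is a mismatch. Palindromic variants (A/T, C/G) are
dropped by default; the `freq` policy orients them by allele frequency
when both frequencies are outside 0.5 ± 0.08. Matching is by variant id
only (positions carried, builds not reconciled).

**Estimators.**

- Wald ratio (k = 1): β_out/β_exp, first-order SE se_out/|β_exp|
  (second-order option adds the exposure-noise term).
- IVW (k ≥ 2): weighted regression through the origin, weights 1/se²_out.
- Correlated IVW: GLS with Σ = diag(se_out)·R·diag(se_out). Near-singular
  R receives a diagonal ridge starting at 10⁻⁶, escalating tenfold to at
  most 10⁻³, after which the fit fails loudly (condition-number cap
  10¹²).
- MR-Egger (k ≥ 3): weighted regression with intercept after orienting
  all β_exp ≥ 0; the intercept is the directional-pleiotropy test.
  Residual scale floored at 1, t reference with k−2 df.
- Weighted median (k ≥ 3): interpolated median at cumulative weight 0.5
  of the ratio estimates, weights from first-order ratio SEs; SE by
  parametric bootstrap (default 1,000 resamples, explicit seed required —
  there is no silent default RNG anywhere in the package).

**IVW dispersion and inference.** The default (`dispersion="wls"`) scales
the fixed-effect SE by √(Q/(k−1)) with no floor and refers the statistic
to t with k−1 df — exact weighted-least-squares inference. The widely
used alternative (`"mre"`): inflate only when Q/df > 1 and use a normal
reference. The default was chosen on calibration grounds: flooring the
dispersion at the fixed-effect level while using normal quantiles makes
the null test conservative at small k (size ≈ 0.039 rather than 0.05 at
k = 10, by direct numerical integration) and pushes CI coverage to
≈ 0.92; the unfloored-t convention has exactly nominal size and coverage
when residual dispersion is proportional to the weights. At very small k
(two instruments, df = 1) the t reference is heavy-tailed and the test
correspondingly cautious; with a supplied LD matrix, retaining more
correlated instruments and using the GLS estimator is the better-powered
route. Confidence intervals use the same reference distribution as the
p-value. Cochran's Q, its df and χ² p-value are always reported.

**Steiger filtering.** Per instrument, r²_exp = z²/(z² + n_exp − 2) vs
r²_out likewise; keep iff r²_exp > r²_out (strict — a tie fails). Sample
sizes come from the summary statistics.

**Multiplicity and tiering.** The decision rule is the fixed two-level
one: p < 0.0003 "global" (0.05/150 genes), p < 0.003 "potential"
(0.05/14 cell types), both thresholds truncated to one significant digit
as printed; boundaries belong to the weaker tier. BH step-up adjusted
p-values (per cell type and across all tests) are computed alongside via
statsmodels but do not drive the tier, matching the printed rule.

## Colocalization

Wakefield approximate Bayes factors per variant,
lABF = ½(log(1−r) + r z²), r = W/(W+V); prior effect variance
W = (0.15·sdY)² for quantitative traits, 0.2² (log-odds) for
case-control — the documented defaults of the standard tooling, exposed
in `ColocInput`. Priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵. Hypothesis weights
are assembled entirely in log space with log-sum-exp (a 200-variant locus
with z ≈ 8 would overflow linear space); H3's pair sum is computed as
log-difference of ΣBF1·ΣBF2 and Σ(BF1·BF2). A single-variant locus has an
empty pair sum: PPH3 is reported as 0 with a `single_variant` flag rather
than NaN. PPH4 ≥ 0.8 is labeled colocalized; the threshold is an
argument.

## Entropy and prioritization

Proportions pᵢ = |βᵢ|/Σ|βⱼ| over non-missing lineages;
H = −Σ pᵢ log₂ pᵢ / log₂ n with 0·log 0 = 0, n counting only tested
lineages — treating a missing lineage as zero would conflate "no effect"
with "not measured". H is snapped to exactly 0 or 1 within 10⁻¹² of the
analytic boundary. Classification: H < 0.5 lineage-specific, H > 0.8
diffuse, otherwise intermediate (the middle band is this package's label;
only the outer bands carry the conventional names). An extra reporting
flag marks H < 0.2, the strikingly restricted band, without affecting
classification or ordering. Ranking is ascending H, ties by descending
mean |β| then symbol. By default the profile should be fed tier-filtered
MR rows (global/potential), via `MRRunResult.significant()`.

Priority scores are the weighted sum of four binary criteria with weights
(+2, +1, +1, +0.5); the reachable grid {0, 0.5, …, 4.5} partitions
exactly into high (≥ 4), medium (3–3.5), low (≤ 2.5). Drug evidence comes
from a static annotation snapshot (gene, drug_id, interaction_type,
source, druggable_class); genes without rows are annotated "undrugged".
No live database is queried.

## Network stage

Edge lists may use (gene_a, gene_b, score) or STRING's
(protein1, protein2, combined_score); scores above 1 are auto-interpreted
as the 0–1000 integer scale. Edges are kept iff both endpoints are in the
gene universe and score ≥ 0.7; duplicates keep the maximum score;
self-loops are dropped. Betweenness is exact unweighted shortest-path
centrality (networkx), pair-normalized with endpoints excluded; hub
ranking is descending BC with degree-then-symbol tie-breaks (k = 10 by
default). Final candidates are the intersection of top hubs with high- or
medium-priority genes, annotated with each gene's maximum PPH4; the full
annotated table is returned rather than a hard-coded candidate count.

## Synthetic data generator

The generator works directly at the summary level on the standardized
scale (unit-variance genotypes and traits), so a desk-scale run has the
same statistical structure as the real design without individual-level
data:

- cis locus of m variants with AR(1) LD, R[i,j] = ρ^|i−j| (default
  ρ = 0.5, m = 50), MAF uniform on (0.05, 0.5];
- causal cis effects b on n_causal variants (default 3) drawn
  N(0, 0.3²) — single-variant F ≈ 90 at the 982-donor eQTL sample,
  matching the strong-instrument regime of retained single-cell eQTLs;
  marginal effects R·b; estimates add MVN(0, se²R) noise with
  se = 1/√n;
- outcome effects θ·(R·b) plus optional direct (pleiotropic) effects on
  a fraction of causal variants, noise at GWAS scale (default
  n_gwas = 50,000; the emulated outcome cohort of 484,598 is one
  argument away).

Defaults are the emulated study's conditions: 14 immune-lineage labels,
n_eqtl = 982, drug-annotation frequency 0.41 (62 of 118 genes drugged in
the emulated analysis). Per-locus RNG streams derive from
(seed, gene, cell type), so any locus regenerates in isolation and a
fixed seed is byte-reproducible.

What it deliberately does not emulate: each gene × cell-type locus is an
independent cis window with its own variant ids, whereas a real outcome
GWAS shares variants across the cell types of one gene (and across nearby
genes); the outcome is a continuous liability, not the binary self-report
trait of a real cohort (MR algebra is identical given β/se); allele
frequencies do not enter the SE model; and conditional independence of
multiple eQTL signals is taken as given rather than re-derived. Passing
tests therefore demonstrate correctness of the estimators and decision
rules under the declared model, not robustness to build mismatches,
strand ambiguity at scale, sample overlap, or mis-specified LD panels.

## Numerical conventions and limitations

- p-values are clipped to (tiny, 1] — extreme z underflows the survival
  function and downstream code requires p > 0.
- TSV output uses 6 significant digits, below estimator noise.
- Tie-breaks are deterministic everywhere (p then variant id in clumping;
  H, mean |β|, symbol in entropy ranking; BC, degree, symbol in hubs).
- The pipeline reports audit counts at every attrition stage and emits
  skipped pairs with a reason instead of dropping them.
- Problem sizes used in the test suite (e.g. 500 replicates for recovery,
  2,000 for size, 100 coloc replicates, 60 hub seeds) were chosen as the
  smallest sizes at which the Monte-Carlo error is comfortably below the
  bands being checked.
- No MR-PRESSO, multivariable MR, reverse-direction scans, SuSiE-style
  multi-signal colocalization, liftover, or proxy-variant lookup.
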