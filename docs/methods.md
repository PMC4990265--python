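# Methods

## The model

Neutral heterozygosity at an autosomal position *x* is modelled through the
competition between mutation and coalescence. A sampled pair of lineages
differs at *x* if a mutation (rate `2u(x)` per generation) occurs before the
pair coalesces, either through drift — at rate `1/(2 Ne B(x))`, where
`B(x) ∈ (0,1]` is the multiplicative reduction in effective size caused by
background selection — or through a sweep forcing coalescence at rate
`S(x)`. Writing `pi0 = 4 Ne u-bar` and `u_rel = u/u-bar`, and measuring the
sweep rate in units of `1/(2 Ne)`, this becomes

    pi(x) = pi0 u_rel(x) / ( pi0 u_rel(x) + 1/B(x) + S_scaled(x) ).

**Background selection.** Each selected position *y* of annotation class
*i*, under heterozygous selection coefficient *t* and deleterious mutation
rate `u_d`, multiplies `B(x)` by `exp(−u_d · t/(t + r(x,y)(1−t))²)` with
`r(x,y)` the genetic distance in Morgans. The approximation is accurate for
strong selection (`2 Ne t >> 1`); for the weakest default grid mass
(`t = 10^-5.5`, `Ne = 10^6`) it is at the edge of its validity, which is the
usual caveat of this model family, not an implementation choice.

**Sweeps.** Each substitution *y* of class *j*, if beneficial with additive
coefficient *s*, contributed coalescence with probability `exp(−r(x,y) τ)`,
where `τ(s, Ne) = 2(ln(4 Ne s) + γ − (4 Ne s)⁻¹)/s` is the
diffusion-approximation fixation time. Substitutions are assumed uniform in
time over a lineage of length *T* generations with one substitution per
substituted site, giving rate `(1/T) Σ_j α(j) Σ_y exp(−r τ)`; `T` enters
only through `T/(2 Ne) = (K/2)/pi0` with *K* the mean substitutions per
neutral site, so the sweep term is proportional to `pi0` — a dependence the
optimiser treats exactly, not as a constant. `τ` uses the genome-average
`Ne` (its dependence is logarithmic, so local `B`-adjustment would change
little). The model ignores interference between sweeps and treats soft or
partial sweeps only insofar as their footprints mimic mixtures of classic
sweeps.

**Discretised DFE.** Both continuous distributions of selection
coefficients are replaced by point masses on a fixed grid (default
`10^-5.5, 10^-4.5, 10^-3.5, 10^-2.5, 10^-1.5`). The BS weights are
deleterious mutation rates per site per generation (optionally bounded per
class by a maximal total rate); the sweep weights are fractions of
substitutions, bounded to sum to at most 1 per class. Adjacent masses trade
off by design; no smoothing or regularisation is applied.

**Composite likelihood.** Pairwise difference indicators are treated as
independent across sites and sample pairs; a site with *k* derived among
*n* alleles contributes `n_diff = k(n−k)` differing and
`n_same = C(n,2) − n_diff` identical pairs, and
`logCL = Σ_x n_diff log pi + n_same log(1−pi)`. Point estimates from
composite likelihood are consistent, but its curvature does not give
standard errors (pairs are correlated through the genealogy), so no
uncertainty intervals are reported; reliability is assessed by window R²,
cross-validation and collated curves instead.

## Lookup tables

`b(x|t,i)` (BS exponent per unit `u_d`) and `s(x|s,j)` (summed sweep
kernel) are independent of the weights, so they are computed once per data
set. Two paths exist:

* **exact** — vectorised per-position sums over every selected bp /
  substitution on the focal chromosome; quadratic cost, used at desk scale
  and as the reference in tests;
* **binned** — geometric distance bins in Morgans (ratio 1.03, first bin
  `1e-9` M): per-bin counts of selected bp are *exact*, obtained from a
  piecewise-linear "selected bp vs genetic position" function (annotation
  blocks cut at map knots), and the kernel is evaluated once per bin at its
  representative distance. Substitution counts per bin are exact integer
  counts. Near-linear cost; used automatically above ~2×10⁸ site×position
  pairs.

Binned-path accuracy: relative error is typically ≲0.5% and worst around a
few percent for entries dominated by a single far selected block (tested
against the exact path); errors average out in the likelihood, which sums
thousands of positions per site. Per-position contributions below
`eps_trunc = 1e-10` (configurable) are truncated via a per-grid-point
distance cutoff; the induced error is bounded by `eps_trunc` times the
number of selected positions.

Zero-recombination map segments would make genetic position non-invertible;
cumulative counts nudge duplicate genetic positions by 1e-18 M to keep
interpolation monotone.

## Estimation

* `u_rel(x)`: substitution fraction at divergence-informative neutral sites
  in a sliding window of 6,000 such sites (configurable) centred on each
  site, divided by the genome mean and renormalised to unit mean. Windows
  shrink symmetrically at chromosome ends down to 1/8 of the window, then
  clip asymmetrically (flagged); pure symmetric shrinkage would degenerate
  to single-site windows at the ends.
* Masks: fitting uses sites with local recombination ≥0.75 cM/Mb outside
  the distal 5% of each arm; prediction extends to >0.1 cM/Mb.
* `Ne`: mean neutral heterozygosity divided by `4 µ` with µ a direct
  mutation-rate estimate. `K`: mean substitutions per neutral site from the
  divergence table.
* Optimisation: bounded L-BFGS-B over `pi0` and the free weight blocks
  (variant `bs`, `cs` or `both`), with BS weights internally rescaled by
  1e8 so all parameters are O(0.01–1) — raw-space bounds were preferred
  over a log transform so exact zeros are representable (null starts,
  sparse truths). Per-class sum constraints are enforced by a quadratic
  penalty plus a final exact projection (feasibility to 1e-12). Analytic
  gradients (verified against finite differences). Multi-start: one null
  start (weights zero, `pi0` at observed mean scaled heterozygosity) plus
  seeded random draws from the constraint box (default 8 starts);
  convergence at relative objective change <1e-12 and projected gradient
  <1e-9 on the per-pair-normalised objective.

A known, genuine flat direction: `pi0` trades off against near-uniform
background selection (strong-*t* mass spread over abundant annotation), as
similar diversity can arise from a larger `pi0` with stronger uniform BS.
With genome-scale data the direction resolves statistically, but on small
simulated genomes fitted weights can wander along this ridge while the
implied diversity map stays correct — tests therefore assert map-level
agreement where parameters are only weakly identified.

## Evaluation statistics

* **Scaled diversity**: per-site heterozygosity divided by `u_rel`,
  normalised by its informative-pair-weighted genome mean; predictions are
  scaled identically.
* **Window R²**: squared Pearson correlation of pair-weighted window means
  of observed vs predicted scaled diversity (non-overlapping windows;
  windows with <100 informative sites dropped by default). Pearson — not
  rank — correlation, as the quantity of interest is explained variance.
* **LOOCV**: for each window, parameters are refit on the complement
  (warm-started at the all-data optimum plus a null start) and the window
  mean is predicted out of sample; out-of-sample R² across windows is
  compared with in-sample R².
* **Collated curves**: every (site, substitution) pair within a maximal
  genetic distance contributes once to a linear distance bin; per-bin
  pair-weighted means of observed/predicted scaled diversity and of the
  added coalescence rates `1/B − 1` (BS) and `S_scaled` (CS).
* **Stratification**: sites sorted by predicted scaled diversity and cut
  into equal-data bins (equal cumulative pair counts; ties broken by
  genomic order); Spearman correlation between bin means; the diversity
  reduction is the ratio of mean observed diversity to the no-selection
  prediction `pi_null = pi0 u_rel/(pi0 u_rel + 1)` (using `pi_null` rather
  than `pi0` itself keeps the ratio exactly 1 in expectation under
  neutrality; the two differ by a factor `1 + pi0 u_rel ≈ 2%`).
* **Mode contributions**: genome means of `1/B − 1` and `S_scaled` over the
  prediction mask, and their shares of the sum.

## The synthetic generator

The generator emulates the full input bundle with known truth, under the
model's own generative law (`n_diff ~ Binomial(C(n,2), pi(x))` in
`independent_pairs` mode — exactly the composite likelihood's implied
model, so recovery tests are well-posed; an `allele_counts` mode draws a
single site frequency from a neutral-SFS-shaped law with the same expected
heterozygosity, giving within-site pair correlation for robustness checks —
exact recovery is not guaranteed there, which the tests document rather
than hide).

Default study conditions: 4 chromosomes × 25 Mb; annotation classes
coding (~20%), UTR (~5–6%), long intron (~15–16%), intergenic; genes drawn
from four architecture types (compact/intronless, long-intron, UTR-rich,
baseline) clustered in 250 kb regions — the compositional heterogeneity
real genomes show, and the basis on which class-specific BS rates are
identifiable at the ~40 kb footprint of `t = 10^-3.5`; recombination
cycling 0.5/1.5/2.5/3.5 cM/Mb in 2.5 Mb segments (placing sites on both
sides of both masking thresholds); substitution densities 2e-3 (amino
acid), 1e-3 (UTR), 5e-4 (intron) per parent bp; a 20-allele sample;
`pi0 = 0.02`, `K = 0.1`, `µ = 5e-9` (so `Ne = 10^6`). True selection:
sweeps at amino-acid substitutions only (4% at `s = 10^-3.5`, 35% at
`10^-5.5`) and purifying selection on coding only (`u_d = 5e-9` at
`t = 10^-3.5`).

The polymorphism panel is a thinned set of synonymous-like sites inside
coding (0.02 per coding bp, ~400k sites genome-wide — ample information at
modest memory and runtime); the divergence panel is denser (0.25 per coding
bp, i.e. essentially all synonymous-like sites, as divergence requires no
population panel). The panel densities matter: with a sparse divergence
panel the 6,000-site proxy window spans megabases and its ~4% sampling
noise becomes spatially correlated at the scale of broad BS footprints,
biasing the apportionment of background selection — an estimation-noise
effect, not a property of the likelihood.

What the generator does **not** emulate: genealogical correlation between
nearby sites (draws are independent given `pi(x)`), demographic change,
selection on the neutral sites themselves, errors in the genetic map or
annotations, and alignment gaps/missing data. Passing recovery tests
therefore demonstrates correctness of the inference machinery under the
model's own assumptions — not robustness to the model misspecifications
real data carry.

## Degenerate inputs and edge rules

Sites with fewer than two alleles are dropped with a warning; a
substitution at the focal site's own position contributes `exp(0) = 1`;
inter-chromosomal distances are undefined by contract; empty collation bins
report count 0 and undefined means; stratification refuses more bins than
sites; `u_rel` is floored at 1e-3 (flagged) before renormalisation;
`fixation_time` refuses `4 Ne s ≤ 1` and warns below 10.

## Known limitations

* No uncertainty quantification (inherent to composite likelihood here).
* The `pi0`–uniform-BS ridge above: `pi0` and strong-selection BS weights
  from small data sets should be read jointly, not marginally.
* The binned path's percent-level kernel error is invisible at likelihood
  scale but would matter if lookup entries were consumed individually for
  single-site analyses; use `method="exact"` there.
* X chromosomes, non-equilibrium demography, partial/soft sweep kernels and
  interference are out of scope.
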