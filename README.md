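# linkedsel

Joint inference of **background selection** and **classic selective sweeps**
from genome-wide neutral polymorphism, functional annotations, lineage
substitutions and a genetic map — and construction of the genome-wide map of
expected neutral diversity those parameters imply.

Selection at one site distorts variation at linked sites, so observed
neutral diversity is shaped simultaneously by purifying selection against
linked deleterious mutations (background selection, BS) and by the
hitchhiking effect of beneficial substitutions (classic sweeps, CS).
`linkedsel` is for population geneticists who want to estimate the
parameters of both modes at once from polymorphism data — rather than
assume one mode — and to obtain a per-site null expectation of diversity
for demographic inference or selection scans.

## Model

Expected neutral heterozygosity at position *x*:

```
pi(x) = pi0 u_rel(x) / ( pi0 u_rel(x) + 1/B(x) + S(x) )
```

* `pi0 = 4 Ne u-bar` — heterozygosity absent linked selection;
* `u_rel(x)` — local mutation rate relative to the genome mean, estimated
  from substitution densities at neutral sites in sliding windows;
* `B(x) = exp( - Σ_i Σ_g w(t_g|i) b(x|t_g,i) )` — the BS factor, with
  `b(x|t,i) = Σ_{y in class i} t / (t + r(x,y)(1-t))²` summing over every
  selected position *y* and `r(x,y)` the genetic distance in Morgans;
* `S(x) = (2 pi0 / K) Σ_j Σ_k w(s_k|j) s(x|s_k,j)` — the sweep coalescence
  rate in units of `1/(2 Ne)`, with
  `s(x|s,j) = Σ_{y in class j} exp(-r(x,y) τ(s, Ne))`, summing over the
  substitutions of class *j*, `τ(s, Ne) = 2(ln(4 Ne s) + γ − (4 Ne s)⁻¹)/s`
  the diffusion-approximation fixation time, and *K* the mean number of
  substitutions per neutral site on the lineage.

The distributions of fitness effects are discretised on a grid of selection
coefficients (default `10^-5.5 … 10^-1.5`, five log-spaced masses): the BS
weights `w(t_g|i)` are deleterious mutation rates per site per generation
and the CS weights `w(s_k|j)` are fractions of class-*j* substitutions that
were beneficial with coefficient `s_k`. Because `b` and `s` do not depend on
the weights they are precomputed once as lookup tables; the composite
log-likelihood over sites and sample pairs,

```
logCL = Σ_x [ n_diff(x) log pi(x) + n_same(x) log(1 − pi(x)) ]
```

is then maximised over `pi0` and the weights (bounded L-BFGS-B,
multi-start, with per-class sum constraints). Model variants with BS only,
CS only, or both are supported, as is an upper bound on the deleterious
mutation rate.

## Worked example

Everything below runs on synthetic data with known ground truth — no
downloads. The generator emulates a 4 × 25 Mb genome (gene models with
coding/UTR/long-intron/intergenic annotation, a piecewise genetic map,
lineage substitutions, a divergence panel and a 20-allele polymorphism
panel) whose true parameters echo the inferred regime in *Drosophila*:
4% of amino-acid substitutions swept with `s = 10^-3.5`, 35% with
`s = 10^-5.5`, and coding sequence under purifying selection with
`u_d = 5e-9` at `t = 10^-3.5`.

```python
from linkedsel.pipeline import run_synthetic_pipeline, evaluate_pipeline
from linkedsel.synthetic_data import SyntheticConfig

res = run_synthetic_pipeline(SyntheticConfig(seed=1))
p = res.fit_result.params
print("pi0:", p.pi0)
print("cs totals:", p.cs_class_totals())
print("bs totals:", p.bs_class_totals())
ev = evaluate_pipeline(res)
print("window R2 (1Mb):", ev["window_r2"])
print("spearman:", ev["stratify"].spearman_rho,
      "pibar/pi0:", ev["stratify"].pibar_over_pi0)
```

prints (about three minutes on one core):

```
pi0: 0.02042512892279464
cs totals: {'nonsyn': 0.4037320019001987, 'utr': 0.0075543676165682, 'intron': 0.1003986361489329}
bs totals: {'coding': 5.891131912329809e-09, 'utr': 8.768189762767269e-11, 'intron': 5.602261611194073e-11, 'intergenic': 1.539737953780086e-10}
window R2 (1Mb): 0.9861448525065011
spearman: 0.9384175784834292 pibar/pi0: 0.7906386221377929
```

Reading the output: the fitted `pi0` (0.0204) recovers the true 0.02 within
2%; the combined fraction of beneficial amino-acid substitutions (0.40)
recovers the true 0.39; the deleterious rate attributed to coding sequence
(5.9e-9) recovers the true 5e-9; the predicted map explains 99% of
diversity variance across 1 Mb windows; and observed diversity is reduced
to 0.79 of its no-linked-selection expectation. The same pipeline is
available from the shell:

```
linkedsel simulate   --workdir run --seed 1
linkedsel precompute --workdir run
linkedsel fit        --workdir run --variant both
linkedsel predict    --workdir run      # BedGraph tracks of the map
linkedsel evaluate   --workdir run      # window R2, strata, mode shares
```

To analyse real data instead, provide BED4 annotations, a genetic-map TSV,
a substitution TSV, a polymorphism table (TSV or VCF) and a divergence TSV
to `linkedsel.genome_data.load_inputs`, then call the same
`build_bs_lookup` / `build_sweep_lookup` / `fit` / `predict_map` functions.

## Layout

* `linkedsel.genome_data` — data model and I/O (annotations, genetic map,
  substitutions, polymorphism, divergence), masking, mutation-rate proxy.
* `linkedsel.selection_effects` — BS and sweep lookup tables (exact and
  distance-binned paths), fixation times, weight combination.
* `linkedsel.inference` — composite likelihood, constrained maximisation,
  parameter containers.
* `linkedsel.evaluation_maps` — diversity maps, window R², leave-one-out
  cross-validation, collated curves, stratification, mode contributions.
* `linkedsel.synthetic_data` — the ground-truth generator.
* `linkedsel.cli` — the `linkedsel` command.

See `docs/methods.md` for the model's assumptions, numerical choices and
known limitations.
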