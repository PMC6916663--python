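# Methods

## The model

Phenotypes of a single trait measured on individuals planted at one of
`S` trial sites are modelled as

```
y = Xβ (+ f·i) + W b + Σ_g Z_g u_g + ε
```

* `β` — grand mean and site contrasts (site 1 is the reference level).
* `f·i` — optional inbreeding-depression covariate: `f` is the genomic
  inbreeding coefficient (proportion of homozygous SNPs per
  individual), `i` its regression coefficient. It is fitted on request
  and tested with a Wald test at α = 0.05; the raw proportion is used
  (no centering), since only the contrast between individuals is
  identifiable next to the intercept.
* `b` — random post-block effects nested in sites, `b ~ N(0, σ²_b,s I)`
  with a separate variance per site.
* `u_g` — one random genetic effect per requested term:
  additive, dominance, and the three first-order epistatic interactions
  (additive×additive, additive×dominance, dominance×dominance), with
  `u_g ~ N(0, Σ_g ⊗ K_g)`, where `K_g` is a relationship matrix
  (pedigree A/D or genomic Ga/Gd/Gaa/Gad/Gdd) and `Σ_g` an across-site
  covariance structure (below).
* `ε` — heterogeneous residuals, one variance per site, always.

Model names follow the BLUP convention: ABLUP-A/AD use pedigree
kernels, GBLUP-A/AD/ADE genomic kernels. Epistasis is only available
with genomic kernels: in a full-sib progeny trial without clonal
replicates the pedigree model cannot separate epistatic from additive
and dominance covariance, while marker-defined kernels can.

### Relationship matrices

* Pedigree additive `A` by the tabular method:
  `A_ii = 1 + A_gh/2`, `A_ij = (A_jg + A_jh)/2`; unknown parents are
  unrelated non-inbred founders; the pedigree is topologically sorted
  internally and cycles are an error.
* Pedigree dominance `D`: `D_ii = 1`,
  `D_ij = (A_gk A_hl + A_gl A_hk)/4` over the two parent pairs.
* Genomic additive `Ga = ZZ'/Σ 2p_i q_i` with the centered coding
  `{aa: −2p, Aa: q−p, AA: 2q}`; genomic dominance
  `Gd = WW'/Σ(2p_i q_i)²` with `{aa: −2p², Aa: 2pq, AA: −2q²}`.
  This dominance parameterization keeps Ga and Gd orthogonal in
  expectation, so their variance components are directly comparable
  with the pedigree A/D scale.
* Epistatic kernels are Hadamard products normalized to trace `n`:
  `Gaa = (Ga#Ga)/(tr(Ga#Ga)/n)` and likewise for Gad, Gdd (and the
  pedigree products Paa/Pad/Pdd).

Allele frequencies default to those observed in the supplied genotype
matrix; externally supplied (e.g. founder) frequencies can be passed
instead. Monomorphic SNPs are a hard error rather than a silent drop so
that `m` stays consistent between Ga, Gd and `f`. All results are
invariant to which allele is labelled A at each SNP (tested).

### Across-site covariance structures

For `S` sites each genetic effect can take one of

| name    | parameters      | site covariance                                  |
|---------|-----------------|--------------------------------------------------|
| IDEN    | 1               | common variance, zero across-site covariance     |
| DIAG    | S               | site-specific variances, zero covariance         |
| CS      | 2               | common variance and common covariance            |
| CS+DIAG | 1 + S           | common covariance, site-specific variances       |
| US      | S(S+1)/2        | unstructured (Cholesky-parameterized, PSD)       |
| FA(0)   | 1 + S           | main-term variance + site-specific variances     |

CS, CS+DIAG and FA(0) admit the decomposition `a = m + me`: a main
effect `m` shared across sites (variance = the common covariance) plus
independent site deviations `me` (M×E). For two sites FA(0) and
CS+DIAG describe the same family of matrices; both are kept because
their parameter meanings differ. FA with k ≥ 1 factors is not
implemented (two-site data cannot identify extra loadings) and raises
`NotImplementedError`. The CS covariance is constrained to
`0 ≤ cov ≤ σ²` so the m + me decomposition always yields non-negative
variances.

IDEN is implemented literally as "common variance, zero across-site
covariance". An equivalent single-vector formulation (one effect shared
by all sites) differs only through relative pairs split across sites;
with each individual planted at one site the within-site likelihood
contributions are identical.

## REML estimation

The restricted log-likelihood

```
logL = −½ [ log|V| + log|X'V⁻¹X| + y'Py + (n−p) log 2π ]
```

is maximized directly over the variance parameters with L-BFGS-B using
the analytic score `∂logL/∂θ_i = −½[tr(P ∂V_i) − y'P ∂V_i P y]` and box
bounds at zero, so null components converge to the boundary rather than
going negative. US structures are optimized through their Cholesky
factor (diagonal bounded at zero), which maintains positive
semi-definiteness throughout. Internally the response is scaled to unit
variance; the reported logL is transformed back to the trait scale.
Numerical choices:

* starting values — the phenotypic variance split equally among the
  active components per site;
* kernel conditioning — 1e−8 jitter added to the diagonal before
  factorization (configurable; kernels failing Cholesky after jitter
  are an error);
* convergence — optimizer relative-ftol 1e−10, projected-gradient
  1e−6, iteration cap 200; non-convergence raises an error carrying the
  likelihood trajectory;
* the logL constant includes `(n−p) log 2π`, so values are comparable
  within this package's models only; AIC = −2 logL + 2 p counts the
  variance parameters (structure parameters + per-site block and
  residual variances), matching the usual mixed-model reporting
  convention for these analyses.

Approximate standard errors of the variance components come from the
inverse average-information matrix at the optimum. BLUPs of every
random effect are recovered as `û = Cov(u, y) P y` for all individuals
in the kernels (phenotyped or not), and the standard errors of
prediction (SEP) of the breeding values as
`sqrt(diag(Var(u) − Cov(u,y) P Cov(u,y)'))`. Cross-validation refits
warm-start from the full-data estimates; with 90% of records shared the
optimum moves little and this roughly halves fitting time without
changing results beyond optimizer tolerance.

Heritabilities use `σ²_p = σ²_a + σ²_d + σ²_i + σ²_e` at each site —
the post-block variance is excluded from σ²_p, while the per-site
percent columns of a variance report divide by the total including the
block variance. The two conventions are reported side by side because
each reconstructs a different published summary of the same fit.

## Cross-validation

`run_cv` masks validation individuals' phenotypes, refits, and predicts
them from one of three bases: M (main effect only), A (M + site
interaction = full site additive value), AD (A + dominance). Predictive
ability is the Pearson correlation between predictions and validation
phenotypes adjusted by the *training* fit's fixed-effect and
block-effect estimates — validation phenotypes never enter the
adjustment. PA is computed per validation site per replication by
pooling all folds' predictions (each individual is validated exactly
once per replication); the reported SE is the SD of replication means
over √reps. Folds are drawn over individuals within the validation
site; an option keeps full-sib families intact. A single seed drives
fold assignment, with per-replication seeds derived deterministically.
In the across-site scenario (train on one full site, predict the
other), the training fit has no fixed/block estimates for the
validation site; predictions carry the training site's genetic values
and the adjustment omits the unavailable block effects (a constant site
offset does not change a correlation). When a variance component sits
at zero the corresponding basis predictions are constant; their PA is
recorded as 0 with a warning rather than left undefined.

## Response to selection

Expected genetic values (EGV = grand mean + site effect + additive +
dominance BLUP) from the pedigree ABLUP-AD fit are the benchmark.
Candidates are ranked by a genomic basis (M, A or AD from GBLUP-AD) or
by the benchmark itself; `RGS(%) = 100·(mean EGV of selected − mean
EGV)/mean EGV`, divided by the cycle length (12.5 years for genomic,
25 for phenotypic selection) for per-year rates. The population mean is
taken on the trait scale including the baseline: percentages against
the near-zero centered-BLUP mean would be unstable and meaningless.
Site-specific EGVs are used by default (a pooled option exists).
Top-k selection ignores co-ancestry constraints.

## Synthetic data generator

The generator emulates a two-site control-pollinated progeny test:

* **mating design** — a partial diallel: default 55 parents, 128
  distinct pairs (each parent in ≥ 1 cross), balanced full-sib
  families; family members are split between the two sites, so site and
  individual are confounded as in a real paired planting.
* **genotypes** — founder SNPs drawn under Hardy–Weinberg with
  frequencies uniform on [0.05, 0.95], then Mendelian gene dropping of
  independent loci (no linkage map, no selection).
* **phenotypes** — per-SNP additive effects drawn per site from a
  correlated normal; an across-site correlation below one *is* the M×E
  signal. Effect variances are set to `σ²_a,s / Σ2pq` so the kernel-
  scale additive variance of the breeding values equals the configured
  component exactly in expectation (the realized variance fluctuates
  with sampling); dominance deviations likewise on the dominance design
  with scale `σ²_d,s / Σ(2pq)²`. Optional epistatic values are built
  from random pairwise products of design columns and rescaled to the
  configured variance. Block effects, heterogeneous residuals and an
  optional inbreeding-depression term complete the phenotype.

Simulating marker effects (rather than drawing genetic values from the
kernels) makes Ga/Gd/M×E arise mechanistically, so pedigree-vs-genomic
comparisons are meaningful. Default variance components follow the
height-like magnitudes of a Northern Swedish two-site spruce trial
(block ≈ 700/1900, additive ≈ 780/1860 with across-site correlation
0.385, dominance 1224 at both sites, residuals ≈ 4050/7520); a
symmetric compound-symmetry preset (`cs_config`: σ²_b = 500,
σ²_a = 1000 with r = 0.6, σ²_d = 600, σ²_e = 3000 per site) serves the
parameter-recovery checks. What the generator does **not** emulate:
linkage and LD between markers (each locus segregates independently),
genotyping error and missingness, spatial field autocorrelation beyond
the block structure, and multi-generation selection. Passing tests
therefore demonstrate correctness of the estimation machinery under the
stated model, not robustness to those real-data features.

## Problem sizes used in the test suite

The default test scale is 128 families × 5 progeny (n ≈ 640 phenotyped
individuals, m = 2,000 SNPs), the package's standing choice for
desk-scale verification. Parameter recovery uses 30 replicate
simulations at that scale; cross-validation behavior checks use 64
families × 10 progeny with 10-fold (ordering property, both sites
averaged) or 5-fold (null checks) single-replication plans; likelihood
oracles run on instances with ≤ 30 records where dense inversion is
exact and cheap. The zero-epistasis boundary check runs at the full
study scale (128 families × 10 progeny, 4,000 SNPs): the first-order
epistatic kernels are near-collinear with the dominance kernel, and at
half scale the restricted likelihood genuinely attains its maximum at
mixtures that place variance on them — a caution that applies equally
to real datasets of that size. The M×E ordering check simulates a
heritability ≈ 0.43 trait (the wood-acoustic-velocity regime, the
paper-scale trait where compound-symmetry M×E modelling matters most)
with interaction variance equal to half the main-effect variance and no
dominance, and fits the additive-only genomic model: the M-vs-A
contrast is then a pure test of the interaction partition, not of
additive/dominance separation.

## Known limitations

* Single-trait (univariate) analyses only; no multivariate REML.
* Dense matrices throughout — suitable to a few thousand individuals;
  no Henderson sparse A-inverse.
* No standard errors for heritability ratios (no delta method).
* FA(k ≥ 1), spatial residual structures and Bayesian estimation are
  out of scope.
* Published-table reconciliation is limited by the rounding of printed
  inputs; the tests document the two cells where printed ratios cannot
  be regenerated from printed components.
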