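# Methods

This note records the scientific choices behind `onestepblend`: the models
implemented, what the simulator does and does not emulate, numerical
decisions, and known limitations.

## Prediction models

All methods fit `y = 1μ + Zg + e` with `g ~ N(0, K σ²_g)` and
`e ~ N(0, D σ²_e)`, `d_ii = (1 − r²_i)/r²_i` for DRP reliability `r²_i`.
The only fixed effect is the overall mean; DRP are already adjusted
pseudo-phenotypes, so no further factors are modeled.

* **GBLUP**: `K = G` (VanRaden method 1) over genotyped animals. Allele
  frequencies for centering are computed from the genotyped animals
  themselves; base-population frequencies are not observable in practice
  and the package does not pretend otherwise. A consequence is that
  `G·1 = 0` exactly — G is rank-deficient by one (see Numerical choices).
* **One-step blending**: `K = H` over all pedigree animals, built by the
  direct block formula. Only `A₂₂⁻¹` is required; `G` is never inverted in
  the construction, matching the algebra of the block equations. An
  optional conditioning step `G* = 0.95·G + 0.05·A₂₂` exists for
  pathologically ill-conditioned G but is off by default, since the block
  formula does not need it.
* **Adjusted one-step blending**: `H` built from `G_a = Gβ + α`, with
  `(β, α)` from the 2×2 moment system matching diagonal and off-diagonal
  averages of `G` to `A₂₂`. `α` is added to **every** element of `G_a`,
  including the diagonal, as the scalar-offset definition implies.

Variance components are re-estimated per method and per trait: each K
defines its own genetic scale, and sharing estimates across methods would
silently couple them.

## REML

The restricted likelihood is maximized in the ratio `λ = σ²_e/σ²_g`:
for fixed λ the genetic variance profiles out analytically, leaving a 1-D
problem solved by bounded Brent search on `log λ ∈ [−12, 12]`, followed by
an optional Nelder–Mead polish of `(log σ²_g, log σ²_e)` (accepted only if
it does not degrade the objective). This reaches the same optimum as an
average-information updater at desk scale while being hard to destabilize.
`converged` is true only for an interior optimum; a fit pinned at the λ
boundary (e.g. a constant response driving `σ²_g → 0`) is returned
flagged, not raised.

## Mixed-model equations and accuracies

Predictions solve the σ²_e-scaled MME
`[1′W1, 1′WZ; Z′W1, Z′WZ + K⁻¹λ][μ̂; ĝ] = [1′Wy; Z′Wy]` with `W = D⁻¹`.
Animals without records (validation cows; any filtered cohort) receive
predictions purely through K. PEV is the g-block diagonal of the inverse
coefficient matrix times σ²_e, and theoretical accuracy is
`√(1 − PEV_i/(K_ii σ²_g))`, clamped to [0, 1].

`K⁻¹` comes from a Cholesky factorization with a jitter ladder
(0, 1e-8, 1e-6, 1e-4 added to the diagonal; the jitter used is recorded on
the fit). Because the sample-frequency-centered G (and hence H) is exactly
singular in the `1` direction, floating-point Cholesky may "succeed" on it
and return a meaningless inverse; the factor's diagonal decay is therefore
checked and an effective condition worse than ~1e12 escalates the ladder.
With the minimal 1e-8 jitter the MME solution coincides with the
generalized-inverse (GLS) solution to well below test tolerances.

## Deregression

EBV are shrunken toward the parent average and double-count parental
information. With own reliability `r²` and parent-average reliability
`r²_PA = (r²_sire + r²_dam)/4` (a missing parent contributes 0 at
reliability 0):

```
r²_own = (r² − r²_PA) / (1 − r²_PA)
DRP    = PA + (EBV − PA) / r²_own,     rel_DRP = r²_own
```

An animal with `r² ≤ r²_PA` carries no own information and is flagged
excluded rather than raising. This is the standard single-animal
parent-average deregression; the exact variant used by any given national
evaluation differs in details (progeny loops, multi-lactation weighting),
so the function sits behind a small interface and the simulator offers a
direct-DRP mode that bypasses it entirely, keeping downstream modules
testable independently of this choice. Inclusion filters use strict
inequalities (a cow at exactly the 0.40 floor is excluded); they are
idempotent, and `rel_DRP ≤ rel_EBV` always.

## The simulator

`popsim` generates the cow-reference design at configurable scale. The
default configuration — 24 genotyped reference sires, 400 genotyped
reference cows, 80 genotyped validation cows of which 40 have
non-genotyped dams with DRP, 20 non-genotyped paternal half-sisters per
sire, 2000 SNPs with MAF ≥ 0.01, 200 QTL, h² = 0.30, DRP reliabilities
uniform between the cohort floor (0.40 cows / 0.80 bulls) and 0.95 — is a
reduced-scale analogue of a national cow-reference evaluation in which
roughly half the validation cows have non-genotyped dams and every
half-sib group descends from a genotyped reference sire.

Mechanics and deliberate simplifications:

* **Genotypes** by gene dropping of unlinked biallelic SNPs: founder
  frequencies `p_j ~ Uniform(maf_min, 1 − maf_min)`, founder alleles
  Bernoulli(p_j), Mendelian sampling thereafter; an unknown parent
  contributes a fresh founder allele. No linkage map, no LD, no genotyping
  error: the estimators consume relationship-matrix moments, which unlinked
  loci already produce. Consequently, passing tests say nothing about
  LD-driven phenomena (e.g. marker-density plateaus on real chromosomes).
* **True breeding values** are additive over a QTL subset, centered and
  scaled to unit variance, so one genetic SD = 1 and `σ²_g = 1` by
  construction.
* **EBV** follow the BLUP shrinkage convention
  `EBV = r²(g + ε)`, `Var(ε) = σ²_g(1 − r²)/r²`, giving
  `corr²(EBV, g) = r²` and regression slope `r²` of EBV on g — the
  property deregression must undo. EBV noise is independent across animals;
  real evaluations induce PEV correlations between relatives' EBV, which
  deregression is designed to mitigate — this structure is deliberately
  absent, so the simulator cannot measure *that* benefit of deregression.
* **DRP**: the default direct mode emits `g + ε` with the stated
  reliability — exactly the observation model the weighted MME assumes,
  with implied `σ²_e = σ²_g` (true λ = 1). The deregress mode instead runs
  the EBV through the deregression module.
* **Reliability distributions**: only the floors are principled (0.40 /
  0.80); the shape above the floor is unknown in general, so
  Uniform(floor, 0.95) is used and exposed as configuration.
* Unknown parents are unrelated founders; all randomness flows from one
  seed through named per-stage substreams, so each stage is independently
  reproducible and per-replicate seeds derive deterministically from the
  master seed.

## Validation

`r_v = corr(ĝ, DRP)/mean(√r²_DRP)` with Pearson correlation, as the
definition states. The denominator averages over exactly the animals in
that row's correlation (subgroup-specific), since it corrects the
attenuation of that same correlation; r_v can therefore exceed 1 and is
reported as computed. Subgroups: all validation cows, cows with genotyped
dams, cows with non-genotyped dams (who also have non-genotyped
half-sisters). The dams-only contrast — refitting one-step with the
half-sisters' DRP removed — is orchestrated by the pipeline so the report
itself stays a pure, deterministic function of its inputs.

## Problem sizes

Defaults are chosen so a full replicated comparison runs on a laptop: the
study replica (1224 animals, ~500 genotyped, 944 reference records, 20
replicates × 4 fits) takes about two minutes; acceptance adds REML
recovery (400 animals × 5 records × 20 replicates), a 5000-animal
deregression calibration, and three 1200-animal founder-heavy populations
for the adjusted-vs-original contrast.

## Known limitations

* Single trait, single fixed effect; no multi-trait or test-day machinery.
* Dense linear algebra throughout — appropriate to ~20 000 animals, not to
  national evaluations (no APY, no sparse A⁻¹ tricks, no iterative
  solvers).
* The deregression is the single-animal parent-average form; MACE-style or
  progeny-loop variants are out of scope.
* β and α land near 1 and 0 on the simulated designs; populations with
  strong pedigree-genomic incompatibility (e.g. unaccounted base-population
  drift) are not emulated, so the adjusted method's behaviour under large
  adjustments is exercised only by direct perturbation in tests.
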