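# Methods

## The generating model and its estimands

Data are drawn from a linear directed acyclic graph. Confounders
`C ∈ R^{n×q}` (default q = 2) are iid standard normal; the exposure is
`E = E0 + 0.2·ΣC`; metabolites are iid standard normal (independent
setting) or rows of `N(0, R)` for a fixed correlation matrix R
(correlated setting); a subset of `n_true = round(prop·p)` columns (the
first columns by default, round half up) receives the mean shift
`+β·E`; the outcome is `O = O0 + 0.8·E + 0.01·ΣC + β·Σ M_true`. The
fixed coefficients 0.2 / 0.8 / 0.01 give moderate exposure confounding,
a strong direct effect and weak outcome confounding.

For a one-unit exposure contrast the mediated effect has closed form:
each true mediator transmits β·β = β², and the total indirect effect
(TIE) is `n_true·β²`. Mediator–mediator correlation does not change
either value (mediator means are linear in E with the same
coefficient), which is verified in the tests against a brute-force
potential-outcome contrast at 10⁶ simulated rows. The component
indirect effect (CIE) of a single mediator is causally interpretable
only when mediators are independent (the recanting-witness problem);
the evaluation layer therefore refuses to emit CIE bias for correlated
scenarios at all.

## The correlation matrix

The target is a positive-definite correlation matrix whose
off-diagonals span roughly [−0.42, 0.45]. A dense draw with iid
off-diagonals in that range is hopelessly indefinite for p ≥ 200
(smallest eigenvalue ≈ −7 at p = 200), and projecting it to the nearest
correlation matrix shrinks the entries to ±0.25 or less, so the matrix
is instead built from a low-rank latent-factor model: each metabolite
loads on k = 8 shared factors with communality 0.5, the Gram of the
loading matrix (diagonal filled to 1 by uniqueness) is positive
definite by construction, and its off-diagonals are rescaled so the
realized minimum/maximum sit at the target range's edges. An
eigenvalue-floor (1e−4) + re-standardize + box-clip repair loop runs
afterwards as a safety net; it is a no-op in practice. Realized
extremes match the target within ~0.05 for p ≥ 20; the off-diagonal
*distribution* is bell-shaped around zero (typical |r| ≈ 0.1 at
p = 600), which we consider more realistic for metabolomics than a
uniform spread, and is in any case forced by positive definiteness.
One fixed matrix per (p, seed) is shared by all scenarios and
replicates, mimicking a single biological correlation structure.

## The three estimators

**MITM.** Both marginal passes adjust for confounders by default (the
DAG confounds E with M and O by construction; a flag disables it).
Selection uses unadjusted p < α = 0.05 in both passes, matching prior
applications of the approach; per-pass Bonferroni and Benjamini–
Hochberg corrections are available. The passes are computed in closed
form: one QR solve for all p features against the common design
(exposure pass) and a Frisch–Waugh–Lovell residualisation for the
outcome pass, so a p = 600 replicate costs ~10 ms.

**HIMA-style.** SIS ranks columns by |cor(M_j, O)| (standardized, ties
by ascending index, zero-variance columns last) and keeps
`d = ⌊2n/ln n⌋` capped at `min(p, n − q − 2)`. The MCP outcome model is
solved by pathwise coordinate descent on the Gram system (numba), 100
log-spaced penalty levels down to 10⁻³·λ_max with warm starts,
concavity γ = 3, E and C unpenalised; the level is chosen by BIC
(`n·log(RSS/n) + log(n)·df`). b-path inference comes from a
post-selection OLS refit on the MCP support — the refit coefficient is
also the one used in the CIE, keeping the estimate and its test
consistent (the released packages differ in unspecified ways here).
Declaration: `max(p_a, p_b) < α/d`.

**HDMA-style.** SIS with `d = ⌊n/ln n⌋` (natural log, the SIS
literature's convention; base 10 available). E and C are partialled out
of O and the screened mediators exactly — for a partially-penalised
Lasso this is equivalent to keeping them unpenalised in the model. The
Lasso level is chosen by 5-fold CV (seeded folds, 50-point path); the
desparsified correction builds a relaxed inverse from node-wise Lasso
regressions, each CV-tuned with the shared fold seed, with
`τ²_j = ‖X_j − X_{−j}γ̂‖²/n + λ_j‖γ̂‖₁`. Standard errors use
`σ̂·sqrt((ΘĜΘ')_jj/n)` with σ̂ from the Lasso residuals
(df = support size); p-values are two-sided normal. Node-wise CV is the
runtime knob: folds advance in lockstep along the path and stop once
the CV error has not improved for five steps, which avoids the dense
small-λ tail (~15× speedup, identical selections in our checks).

## The evaluation study

36 scenarios per mediator-set size: ids 1–18 correlated, 19–36
independent; within each block of 18, ids 1–9 use β = 0.1 and 10–18
β = 0.3, ordered by the proportion of true mediators (2, 5, 10%) and
then sample size (250, 500, 1000). Replicate streams derive from
`SeedSequence(base_seed, spawn_key=(scenario_id, replicate))`, so runs
are reproducible bitwise and invariant to worker count; every method
sees the identical replicate. Failures are recorded as missing rows,
never dropped. Summaries use the sample (n−1) SD.

CIE bias is recorded under two conventions: `cie_bias` averages
`(estimate − β²)` over the *selected* true mediators (replicates
selecting none contribute nothing), and `cie_bias_all` averages over
*all* true mediators with unselected ones counting as estimate 0. The
first isolates estimation quality given selection (winner's curse makes
it ≥ 0 for MITM at both effect sizes); the second folds sensitivity
into the bias and is the convention under which strong-signal settings
show the large negative CIE biases reported for this kind of study.

## What a green test does and does not establish

The generator emulates the stated world exactly: Gaussian features,
linear effects, fixed coefficients, one fixed correlation matrix, no
redundant ion species, instrument drift, missingness or skewness. Green
metrics therefore certify the estimators' behaviour under that world,
not under real untargeted metabolomics data. Two behaviours are
structural and worth noting: (1) with one fixed correlation matrix, the
sign of MITM's TIE bias in correlated scenarios depends on the realized
correlation sum within the true-mediator block (omitted-mediator bias
of the marginal outcome pass), so underestimation there is a property
of a particular matrix draw, not of the method; (2) MITM with
unadjusted double significance is strictly the most liberal selector
evaluated, so its sensitivity cannot fall below that of the
Bonferroni-corrected joint methods under these rules.

## Numerical choices and degenerate inputs

Coordinate descent converges when the largest coefficient change in a
sweep is < 10⁻⁷ (10⁻⁶ node-wise); non-convergence raises with the
penalty level. Zero-variance mediator columns screen last with
statistic 0; rank-deficient designs raise naming the offending column;
exact fits (zero residual variance) give p = 0 for nonzero coefficients
and p = 1 for zero ones. β = 0 configs are valid and produce null
worlds used by the calibration tests. `n_true` rounding is half-up and
a config with `n_true < 1` or `n_true ≥ p` is rejected.

## Defaults

| parameter | default | why |
|---|---|---|
| q (confounders) | 2 | smallest set exercising the ΣC terms |
| α | 0.05 | conventional; all selection rules derive from it |
| MITM correction | none | matches prior applications of the approach |
| HIMA d | ⌊2n/ln n⌋ | the screening convention of the joint methods' literature |
| MCP γ | 3 | standard concavity default |
| MCP λ path | 100 pts to 10⁻³λ_max, BIC | stated study-design choice |
| HDMA d | ⌊n/ln n⌋ (ln) | printed size rule, natural-log reading |
| CV folds | 5 (node-wise and Lasso) | runtime/stability compromise |
| replicates | 1000 (config default) | the study's nominal count; evaluation runs here use 25–200 |

## Known limitations

Binary or survival outcomes, bootstrap TIE intervals, alternative
debiasing schemes (ridge projection), pathway-level aggregation and
exposure-induced mediator–outcome confounding (g-methods) are out of
scope. The node-wise early-stopping rule trades an exactly reproducible
λ grid for speed; its stopping point is deterministic given the data
and seed, so reproducibility is unaffected.
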