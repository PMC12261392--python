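# Methods

## Model

`survrrr` fits a reduced-rank proportional-hazards model to multi-outcome
survival data. For Q time-to-event outcomes observed on the same n subjects,
each outcome q is given its own stratified Cox model

    h_q(t; x) = h_q0(t) * exp(b_q' x),        b_q = column q of B (P x Q),

and the coefficient matrix is constrained to rank at most R through the
factorization B = A Γ', with A (P x R) the predictor loadings shared by all
outcomes and Γ (Q x R) the per-outcome loadings on the R latent factors. The
quantity α_r' x is the *rank score* of subject x on factor r: a single
data-driven risk score (R = 1) or several (R > 1) that drive all outcomes
jointly. Baseline hazards h_q0 are left unspecified and never estimated; all
information enters through the stratified partial likelihood, the sum over
outcomes of the ordinary Cox partial likelihoods with risk sets formed
within outcome only. Ties are handled with the Breslow approximation, and
risk sets are counting-process style ({j : entry_j < t <= exit_j}), so
left-truncated / age-scale data are expressible; entry defaults to 0.

Both factors carry a lasso penalty with a single strength λ (the scaling
freedom (A, Γ) -> (cA, Γ/c) means separate λ_A, λ_Γ add nothing), so the
fitted criterion is the penalized log partial likelihood

    l(A Γ') − λ n (|A|_1 + |Γ|_1),

reported throughout on the deviance scale per subject,

    O = −2 l(A Γ') / n + 2 λ (|A|_1 + |Γ|_1),

where n is the number of subjects. The per-subject scaling makes λ
comparable across sample sizes; published λ values from other software are
on other scales and not directly comparable. The ℓ1 penalty is not
rotation-invariant, so unlike ridge or unpenalized reduced-rank models, the
lasso factorization is unique up to column permutation, joint sign flips,
and column rescaling — precisely the transformations `canonicalize` fixes.

## Estimation

Estimation alternates two penalized stratified Cox fits until the penalized
deviance stops improving:

* **A-step** (Γ fixed): covariates γ_qr · x_p, one coefficient per (p, r);
  design column order is k = r·P + p.
* **Γ-step** (A fixed): covariates α_r' x interacted with outcome
  indicators. Because risk sets never cross outcomes this joint fit
  decouples into Q independent R-covariate problems; the implementation
  fits the joint block design, and the equivalence is asserted in tests.

Each half-step is solved by IRLS with cyclic coordinate descent and
soft-thresholding on the working weighted least-squares problem,
safeguarded by step halving on the exact penalized objective, with a KKT
check (tolerance 1e-7) at exit and at most 100 IRLS rounds. A returned
half-step solution is never worse than its warm start, which makes the
outer penalized-deviance trace non-increasing by construction up to
floating-point noise. The outer loop stops when the improvement drops below
`tol` (default 1e-6) — or when it turns *negative*, which near convergence
only reflects numerical noise; because of that rule the fit returns the
best-objective iterate rather than the last one. Inner-solver
non-convergence is propagated as `converged=False`, never raised: small-λ
fits legitimately fail and the path driver must see that.

An optional `rebalance` step rescales each active column by
c_r = sqrt(|γ_r|_1 / |α_r|_1) after every full iteration. It leaves B and
the likelihood unchanged, never increases the penalty, and speeds
convergence; it is off by default so the plain alternating scheme is the
reference behavior.

`canonicalize` maps a factorization to the representative of its
equivalence class: active columns are rebalanced to equal ℓ1 norms (the
penalty-minimizing scaling), sorted by decreasing ||γ_r||_2 (ties by
||α_r||_2), and sign-flipped so the largest-|·| outcome loading is
positive; columns with an all-zero factor are placed last untouched. The
map preserves B to 1e-12 and is idempotent.

A rank-R model has R(P+Q−R) free parameters (R(P+Q) minus the R^2
dimensions of the transformation group), exposed as `n_parameters_`.

## Penalty paths, out-of-sample deviance, rank choice

Out-of-sample fit uses the likelihood-difference construction: evaluate the
log partial likelihood at the trained B on the training set and on the full
(train + test) data and take

    D_test = −2 (l_full − l_train) / n_test .

Evaluating the difference avoids the degenerate test-only partial
likelihood that arises when a test event time appears in no training risk
set. `n_test` counts distinct test subjects — the unit of the split —
rather than long-format rows; `normalization="rows"` switches conventions.
Null deviances (B = 0) are computed by the same formulas.

λ sequences are log-spaced from λ_max, the KKT threshold at which the first
A-step (at the initial Γ, A = 0) is exactly zero, down to
λ_max · min_ratio. The Γ-step has its own threshold, but in the P >> Q
regime this model targets, the A-step dominates and defines the boundary.

The path is fitted from large to small λ with warm starts: the next fit's
Γ(0) is the previous solution plus a small constant ε (default 1e-2 on the
standardized scale) added to every entry, so a collapsed column is revived
and the model can jump back to the specified rank. Two refinements address
a structural weakness of the alternating scheme — the all-zero
factorization is a stationary trap: for moderate λ the A-step may produce a
weak A whose rank scores are too small for any Γ coefficient to survive,
even though a self-sustaining nonzero optimum exists at that λ.

1. *Warm-start scale preservation.* A column of Γ-hat that is entirely zero
   carries no scale information, so it inherits its column of the current
   initialization rather than restarting at bare ε. Otherwise one full
   collapse shrinks the warm start to the ε scale and the λ at which the
   model re-activates depends on the collapse history instead of the data.
2. *Backward refinement sweep* (default on). After the forward sweep, each
   λ is refitted warm-started from the solution at the next-smaller λ, and
   the fit with the better *training* objective is kept. This is plain
   multi-start optimization of the penalized criterion — the test deviance
   plays no part in the choice — and it removes the init-scale dependence
   of where along the path the model activates, which would otherwise make
   paths fitted at different ranks non-comparable.

If a fit fails to converge, the remaining (smaller) λs are skipped and
flagged. A run whose train-deviance curve departs from the pointwise
minimum across runs by more than 10x `tol` at any shared λ is flagged
divergent (`flag_divergent_runs`).

Rank selection compares candidate ranks by their best converged test
deviance across runs and λs, smallest rank winning ties. "Tie" is equality
within `tie_tol` (default 1e-3 on the per-subject deviance scale): a
higher-rank model contains the lower-rank one, so on data of lower true
rank the two best fits are the same model up to fitting noise, and a strict
floating-point argmin would pick a rank at random; the tolerance is
commensurate with the ~1e-3 elementwise agreement of B across independent
runs at the default fit tolerances. Selecting on training deviance is
impossible by construction — a higher rank never fits training data worse —
which is why the package requires a held-out set (K-fold cross-validation
is a natural alternative for small data; only the single split is
implemented).

## Synthetic data generator

The generator realizes the model directly, with every deviation from real
cohort data chosen to keep closed-form checks available:

* predictors: multivariate normal with AR(1) correlation
  Cov[x_p, x_p'] = ρ^|p−p'| and unit variances (already standardized);
* truth: A_true with a `sparsity` fraction of all-zero rows, nonzero
  entries N(0,1), columns scaled to unit ℓ2 norm; Γ_true all positive,
  U(0.6, 1.4) by default — the signal size rides on Γ;
* event times: exponential given x, i.e. constant baseline hazards h_q0
  (a Weibull shape parameter exists for robustness runs), so marginal event
  fractions have closed forms used by the tests;
* censoring: administrative at a fixed horizon; one outcome (the last, by
  default) may act as death and additionally censors every other outcome —
  the semi-competing layout in which death terminates disease follow-up but
  diseases do not censor each other. Dependence between death and disease
  flows through the shared score only; there is no extra frailty.

Defaults (n = 2000, P = 20, Q = 4, R_true = 1, sparsity 0.6, ρ = 0.5,
h_q0 = 0.02, horizon 10) put per-outcome event fractions in the 10–30%
range. The generator does not emulate real-cohort features such as
non-Gaussian biomarker distributions, informative censoring beyond death,
covariate-dependent entry, or measurement error, so passing tests show the
estimator recovers the model's own structure — not that the model is right
for any particular cohort.

## Study sizes used by the test suite and acceptance script

Chosen as the smallest sizes at which the checked phenomena are stable:
oracle-equivalence fits at n = 200 (P = 5, Q = 2); likelihood and deviance
oracles on instances of n <= 40 against double-loop evaluation (agreement
to 1e-10); monotonicity over 20 fits at n = 250; the recovery experiment at
the generator defaults, 10 replicates, candidate ranks {1, 2} on one shared
λ sequence (n_lambda = 10, min_ratio = 1e-3) per the comparability point
above; boundary behavior at n = 400 over 10 seeds.

## Known limitations

* No standard errors or confidence intervals: the penalization biases
  coefficients and invalidates naive inference.
* Linear effects only; lasso only (the per-coefficient `penalty_weight`
  hook leaves room for adaptive-lasso-style extensions, ridge/group-lasso
  are not implemented).
* The alternating objective is non-convex in (A, Γ); the path machinery
  (warm starts, ε revival, backward sweep, multiple runs) makes the global
  optimum likely but not guaranteed — the multi-run overlap diagnostic is
  the practical check.
* Very small λ fits can legitimately fail to converge; they are flagged,
  not hidden.
* Time scale is whatever the records encode (age or time-on-study); the
  package supports delayed entry but does not choose a scale for you.
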