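# Methods

## Model

An evaluation run of a single-label multi-class classifier produces an
r×r confusion matrix (rows = predicted class, columns = true class; the
canonical orientation everywhere in this package, with a `rows-true`
flag for transposed inputs). The counts (n₁₁, …, n_rr) are modelled as
**one multinomial draw** of size n with cell probabilities
p = (p₁₁, …, p_rr): samples are i.i.d. and each contributes exactly one
cell. The MLE is the plug-in p̂_ij = n_ij/n, and by the multivariate CLT

    √n (p̂ − p) →d Normal(0, Σ),    Σ = diag(p) − p pᵀ.

Per-class rates are TPᵢ = p_ii, FPᵢ = Σ_{j≠i} p_ij (off-diagonal row
sum), FNᵢ = Σ_{j≠i} p_ji, so TPᵢ + FPᵢ = p_i· and TPᵢ + FNᵢ = p_·i.
The aggregate scores are

    miF1   = Σᵢ p_ii                           (= miP = miR),
    maF1   = (2/r) Σᵢ p_ii / (p_i· + p_·i),
    maF1*  = 2 maP maR / (maP + maR),
    maP    = (1/r) Σᵢ p_ii / p_i·,   maR = (1/r) Σᵢ p_ii / p_·i.

## Delta-method variances

For a differentiable score f, Var(f(p̂)) ≈ gᵀΣg/n with g = ∇f(p).
Because each row of Σ sums to zero, the quadratic form simplifies to
Σ g²p − (Σ gp)², which is how all closed forms are evaluated. The
gradients, treating the r² cells as unconstrained coordinates (the
constraint lives in Σ), are:

* miF1: g_kl = 1{k=l}, giving Var = T(1−T)/n with T = Σ p_ii.
* maF1, with sᵢ = p_i· + p_·i (a cell p_kl enters s_k and s_l, twice on
  the diagonal):
  g_kl = (2/r)[1{k=l}/s_k − p_kk/s_k² − p_ll/s_l²].
* maF1*: chain rule through h(P, R) = 2PR/(P+R), ∂h/∂P = 2R²/(P+R)²,
  ∂h/∂R = 2P²/(P+R)², with
  ∂maP/∂p_kl = (1/r)[1{k=l}/p_k· − p_kk/p_k·²] and
  ∂maR/∂p_kl = (1/r)[1{k=l}/p_·l − p_ll/p_·l²].
  The component forms reported in the maF1* diagnostics reduce to
  Var(maP̂) = (1/r²) Σᵢ p_ii FPᵢ / p_i·³ / n (and symmetrically for
  maR̂), and
  Cov(maP̂, maR̂) = (1/r²)[Σᵢ FPᵢ p_ii FNᵢ/(p_i·² p_·i²)
  + Σ_{i≠j} p_ii p_ij p_jj/(p_i·² p_·j²)]/n — note the **column** margin
  p_·j in the cross term.

Wald intervals use the exact normal quantile (1.959964… at α = 0.05)
and are **not clipped to [0, 1] by default**; `clip=True` truncates and
flags. On the boundary (e.g. a perfect classifier) the variance is
exactly 0 and the interval degenerates to a point, with a logged
warning — the large-sample theory is silent there.

### The finite-difference oracle

`delta_variance_numeric` recomputes any score's variance with central
differences on each cell separately, **without renormalizing** the
perturbed table (renormalizing would project the gradient onto the
simplex twice, since Σ already encodes Σp = 1). It is the independent
check that certifies the analytic gradients: tests require agreement to
1e-6 relative on ≥ 50 random strictly positive tables, r ∈ {3,…,6};
observed agreement is ~1e-10. Default step 1e-6 balances truncation
(O(step²·f‴)) against cancellation (O(ε/step)) for cells in roughly
[0.002, 1]; it is configurable, and scores that blow up at a perturbed
point raise an explicit oracle error advising a smaller step.

## Degenerate and undefined cases

* A class absent from **both** margins makes its F1ᵢ a 0/0, so maF1
  raises a named error by default; `drop_empty_classes=True` deletes
  that all-zero row/column pair and averages over the r′ < r remaining
  classes, with a logged warning. Dropping silently would change r and
  hence the score, so it is opt-in.
* A class with p_i· + p_·i > 0 but p_ii = 0 has F1ᵢ = 0 — the formula
  is well defined and no special-casing is applied.
* maF1* requires **every** margin positive; a zero row or column margin
  raises an undefined-estimator error (per-class precision or recall is
  0/0). In the simulation this is replicate-level data, not an error.

## Simulation engine

Confusion matrices are drawn as multinomial vectors
(`numpy.random.Generator.multinomial`) from a true table; for each
replicate the plug-in estimate and delta-method variance of each
measure are computed by vectorized closed forms (a test pins them to
the scalar path), and the (1−α) Wald interval is checked for closed
containment of the analytic truth. Three built-in 3-class scenarios are
provided: (1) balanced, diagonal 8/30 and off-diagonal 1/30, all true
scores 0.80; (2) one dominant well-classified class, true scores
(0.72, 0.50, 0.51); (3) one dominant class with high precision but
recall 0.40, true scores (0.48, 0.44, 0.55). Custom scenarios are any
probability table summing to 1 within 1e-9.

**Undefined-replicate policy.** At small n some replicates have an
undefined maF1 (an empty class) or maF1* (a zero margin). The policy is
explicit and switchable: `drop` (default) removes them from the
coverage denominator; `noncover` counts them as misses. Both counts are
reported. Our simulations show `drop` reproduces the published small-n
coverage values, while `noncover` depresses the small-n maF1* cells by
up to ~0.13, so `drop` is the default.

**Seeding.** One master seed spawns an independent
`numpy.random.SeedSequence([seed, crc32(scenario), n])` substream per
(scenario, n) cell, so any single grid cell is reproducible without
rerunning the grid, and the grid equals the cell-by-cell runs exactly.

**Problem sizes.** The default replicate count is 10⁵ per cell. At 10⁵
the Monte-Carlo standard
error of a coverage near 0.95 is ≈ 0.0007, small enough to check
3-decimal coverage values within 3 standard errors, and a full
(3 scenarios × 6 sample sizes) grid runs in well under a minute. The
Monte-Carlo variance validation uses 10⁴ tables at n = 5000, where the
normal-approximation standard error of a sample variance,
s²·√(2/(m−1)), is ~1.4% of the value being checked.

## What the simulations do and do not show

The generator emulates exactly the sampling model the variance theory
assumes: i.i.d. single-label classifications with a fixed true cell
distribution. Real evaluations often violate this — correlated samples
(many epochs per subject in sleep staging), distribution shift between
evaluation sets, or classifiers tuned on the same data. Passing
coverage tests therefore validates the delta-method algebra and the
large-sample approximation, not the applicability of the multinomial
assumption to any particular study; with clustered data the intervals
here will be anti-conservative.

## Known limitations

* Wald intervals undercover for n ≲ 100 (empirically ~0.79 at n = 25
  under an unbalanced truth) and degenerate at boundary estimates; no
  small-sample correction (bootstrap, Bayesian HDI) is implemented.
* Single-label classification only: no multi-label, no support-weighted
  F1, no Fβ for β ≠ 1, and no two-classifier hypothesis tests.
* Variances are O(1/n) plug-in estimates; for extremely sparse tables
  (cells ≈ 0 but margins > 0) the normal approximation can be poor even
  at moderate n.
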