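r"""Delta-method variances and Wald confidence intervals for F1 scores.

The observed counts (n_11, ..., n_rr) are modelled as a single multinomial
draw of size n with cell probabilities p = (p_11, ..., p_rr) (row-major).
By the multivariate CLT,

    sqrt(n) (p_hat - p)  ~  Normal(0, Sigma),    Sigma = diag(p) - p p^T,

and for a smooth scalar score f(p) the delta method gives

    Var(f(p_hat)) ~= g^T Sigma g / n,        g = grad f(p).

Because every row of Sigma sums to zero, the quadratic form reduces to

    g^T Sigma g = sum_kl g_kl^2 p_kl - (sum_kl g_kl p_kl)^2,

which is how the closed forms below are evaluated (with analytic
gradients).  :func:`delta_variance_numeric` recomputes the same quantity
with central finite differences on the unconstrained r^2 coordinates —
the gradient is taken *without* renormalizing the perturbed table, since
Sigma already encodes the sum-to-one constraint — and serves as an
independent oracle for the closed forms.

Wald intervals are ``estimate ± z_{1-alpha/2} * se`` and are not clipped
to [0, 1] unless requested.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import stats

from .confusion_io import ConfusionCounts, ProbabilityTable, normalize
from .errors import InputError, OracleError, UndefinedEstimatorError
from .point_metrics import macro_f1, macro_f1_star, micro_f1

__all__ = [
    "F1Estimate",
    "multinomial_covariance",
    "var_micro",
    "var_macro",
    "var_macro_star",
    "delta_variance_numeric",
    "confidence_interval",
    "estimate_measure",
    "all_estimates",
    "MEASURES",
]

logger = logging.getLogger(__name__)

MEASURES = ("miF1", "maF1", "maF1star")


@dataclasses.dataclass(frozen=True)
class F1Estimate:
    """Point estimate, delta-method variance, and Wald CI for one measure."""

    measure: str
    estimate: float
    variance: float
    se: float
    ci_lower: float
    ci_upper: float
    alpha: float
    z: float
    n: int | None = None
    r: int | None = None
    clipped: bool = False
    #: for maF1*: {"var_maP", "var_maR", "cov_maP_maR", "maP", "maR"}
    components: dict | None = None


def multinomial_covariance(pt: ProbabilityTable) -> np.ndarray:
    """Sigma = diag(p) - p p^T on the row-major flattened r^2 cell vector."""
    p = pt.p.ravel()
    return np.diag(p) - np.outer(p, p)


def _quadratic_form(grad: np.ndarray, p: np.ndarray) -> float:
    """g^T (diag(p) - p p^T) g, exploiting the rank-1 structure."""
    gp = float(np.sum(grad * p))
    return float(np.sum(grad * grad * p) - gp * gp)


def var_micro(pt: ProbabilityTable, n: int) -> float:
    """Var(miF1_hat) = T (1 - T) / n with T = trace(p)."""
    _check_n(n)
    t = micro_f1(pt)
    v = t * (1.0 - t) / n
    if v == 0.0:
        logger.warning(
            "miF1 estimate is on the boundary (%g): variance 0, "
            "Wald interval degenerate", t,
        )
    return v


def _macro_gradient(p: np.ndarray) -> np.ndarray:
    """Gradient of maF1 = (2/r) sum_i p_ii / (p_i. + p_.i) w.r.t. each cell.

    A cell p_kl enters the margin sum s_i = p_i. + p_.i for i = k and
    i = l (twice when k = l), and the numerator only when k = l:

        d maF1 / d p_kl = (2/r) [ 1{k=l} / s_k - p_kk / s_k^2 - p_ll / s_l^2 ].
    """
    r = p.shape[0]
    d = np.diag(p)
    s = p.sum(axis=1) + p.sum(axis=0)
    a = d / s**2
    grad = -(2.0 / r) * (a[:, None] + a[None, :])
    grad[np.diag_indices(r)] += (2.0 / r) / s
    return grad


def var_macro(pt: ProbabilityTable, n: int) -> float:
    """Delta-method Var(maF1_hat).

    Computed as the multinomial quadratic form of the analytic maF1
    gradient; raises on degenerate (empty) classes just as
    :func:`~f1ci.point_metrics.macro_f1` does.
    """
    _check_n(n)
    macro_f1(pt)  # raises DegenerateClassError when a class is empty
    grad = _macro_gradient(pt.p)
    return _quadratic_form(grad, pt.p) / n


def var_macro_star(
    pt: ProbabilityTable, n: int, return_components: bool = False
):
    """Delta-method Var(maF1*_hat), optionally with its components.

    The macro precision and recall have gradients

        d maP / d p_kl = (1/r) (1{k=l} / p_k.  -  p_kk / p_k.^2),
        d maR / d p_kl = (1/r) (1{k=l} / p_.l  -  p_ll / p_.l^2),

    giving (after the multinomial quadratic form, all divided by n)

        Var(maP_hat) = (1/r^2) sum_i p_ii FP_i / p_i.^3 / n,
        Var(maR_hat) = (1/r^2) sum_i p_ii FN_i / p_.i^3 / n,
        Cov          = (1/r^2) [ sum_i FP_i p_ii FN_i / (p_i.^2 p_.i^2)
                       + sum_{i != j} p_ii p_ij p_jj / (p_i.^2 p_.j^2) ] / n,

    combined through the harmonic-mean map h(P, R) = 2PR/(P+R):

        Var(maF1*_hat) = 4 [ R^4 Var(maP) + 2 P^2 R^2 Cov + P^4 Var(maR) ]
                         / (P + R)^4.

    Requires all margins positive (otherwise maF1* itself is undefined).
    """
    _check_n(n)
    _, ma_p, ma_r = macro_f1_star(pt)  # raises on zero margins
    p = pt.p
    r = p.shape[0]
    d = np.diag(p)
    rm = p.sum(axis=1)  # p_i.
    cm = p.sum(axis=0)  # p_.i
    fp = rm - d
    fn = cm - d

    var_map = np.sum(d * fp / rm**3) / r**2 / n
    var_mar = np.sum(d * fn / cm**3) / r**2 / n
    off = (np.outer(d / rm**2, d / cm**2) * p).sum() - np.sum(
        d * d / (rm**2 * cm**2) * p.diagonal()
    )
    cov = (np.sum(fp * d * fn / (rm**2 * cm**2)) + off) / r**2 / n

    if ma_p + ma_r == 0:
        variance = 0.0
    else:
        denom = (ma_p + ma_r) ** 4
        variance = (
            4.0
            * (ma_r**4 * var_map + 2.0 * ma_p**2 * ma_r**2 * cov + ma_p**4 * var_mar)
            / denom
        )
    variance = max(variance, 0.0)
    if not return_components:
        return variance
    return variance, {
        "var_maP": var_map,
        "var_maR": var_mar,
        "cov_maP_maR": cov,
        "maP": ma_p,
        "maR": ma_r,
    }


def delta_variance_numeric(
    score_fn, pt: ProbabilityTable, n: int, step: float = 1e-6
) -> float:
    """Finite-difference delta-method variance (the closed forms' oracle).

    The gradient of ``score_fn`` is taken by central differences on each of
    the r^2 cells independently; the perturbed table is *not* renormalized,
    because the multinomial covariance already encodes the sum-to-one
    constraint.  Returns g^T (diag(p) - p p^T) g / n.
    """
    _check_n(n)
    if step <= 0:
        raise InputError(f"step must be positive, got {step}")
    p = pt.p
    grad = np.empty_like(p)
    for k in range(p.shape[0]):
        for l in range(p.shape[1]):
            hi = p.copy()
            lo = p.copy()
            hi[k, l] += step
            lo[k, l] -= step
            try:
                f_hi = score_fn(ProbabilityTable._unchecked(hi, pt.class_labels))
                f_lo = score_fn(ProbabilityTable._unchecked(lo, pt.class_labels))
            except Exception as exc:
                raise OracleError(
                    f"score undefined at perturbed cell ({k}, {l}) with "
                    f"step {step}; try a smaller step"
                ) from exc
            if not (np.isfinite(f_hi) and np.isfinite(f_lo)):
                raise OracleError(
                    f"score non-finite at perturbed cell ({k}, {l}) with "
                    f"step {step}; try a smaller step"
                )
            grad[k, l] = (f_hi - f_lo) / (2.0 * step)
    return _quadratic_form(grad, p) / n


def confidence_interval(
    estimate: float,
    variance: float,
    alpha: float = 0.05,
    clip: bool = False,
    measure: str = "",
    n: int | None = None,
    r: int | None = None,
    components: dict | None = None,
) -> F1Estimate:
    """Wald interval ``estimate ± z_{1-alpha/2} sqrt(variance)``.

    The exact normal quantile is used (1.959964... at alpha = 0.05).  With
    ``clip=True`` the bounds are truncated to [0, 1] and flagged.
    """
    if not 0.0 < alpha < 1.0:
        raise InputError(f"alpha must be in (0, 1), got {alpha}")
    if variance < 0:
        raise InputError(f"variance must be >= 0, got {variance}")
    z = float(stats.norm.ppf(1.0 - alpha / 2.0))
    se = float(np.sqrt(variance))
    lower = estimate - z * se
    upper = estimate + z * se
    clipped = False
    if clip:
        lo_c, up_c = max(lower, 0.0), min(upper, 1.0)
        clipped = (lo_c, up_c) != (lower, upper)
        lower, upper = lo_c, up_c
    return F1Estimate(
        measure=measure,
        estimate=float(estimate),
        variance=float(variance),
        se=se,
        ci_lower=float(lower),
        ci_upper=float(upper),
        alpha=float(alpha),
        z=z,
        n=n,
        r=r,
        clipped=clipped,
        components=components,
    )


def estimate_measure(
    source: ConfusionCounts | ProbabilityTable,
    measure: str,
    n: int | None = None,
    alpha: float = 0.05,
    clip: bool = False,
) -> F1Estimate:
    """Point estimate + delta-method Wald CI for one measure.

    ``source`` is either a :class:`ConfusionCounts` (n taken from the
    table) or a :class:`ProbabilityTable` with ``n`` given explicitly.
    ``measure`` is one of ``"miF1"``, ``"maF1"``, ``"maF1star"``.
    """
    if isinstance(source, ConfusionCounts):
        pt = normalize(source)
        n = source.n
    else:
        pt = source
        if n is None:
            raise InputError("n is required when estimating from probabilities")
    components = None
    if measure == "miF1":
        est = micro_f1(pt)
        var = var_micro(pt, n)
    elif measure == "maF1":
        est = macro_f1(pt)
        var = var_macro(pt, n)
    elif measure in ("maF1star", "maF1*"):
        est, _, _ = macro_f1_star(pt)
        var, components = var_macro_star(pt, n, return_components=True)
        measure = "maF1star"
    else:
        raise InputError(f"unknown measure {measure!r}; choose from {MEASURES}")
    return confidence_interval(
        est, var, alpha=alpha, clip=clip, measure=measure, n=n, r=pt.r,
        components=components,
    )


def all_estimates(
    source: ConfusionCounts | ProbabilityTable,
    n: int | None = None,
    alpha: float = 0.05,
    clip: bool = False,
    measures=MEASURES,
) -> list[F1Estimate]:
    """Estimates for several measures at once (in the order requested)."""
    return [
        estimate_measure(source, m, n=n, alpha=alpha, clip=clip)
        for m in measures
    ]


def _check_n(n) -> None:
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise InputError(f"n must be a positive integer, got {n!r}")
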