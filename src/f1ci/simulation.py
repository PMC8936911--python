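"""Multinomial table simulation and coverage-probability study.

Confusion matrices are drawn as single multinomial samples of size n from
a true cell-probability table; for each replicate the delta-method Wald
interval for each requested F1 measure is formed and checked for
containment of the analytic true score.  Three built-in 3-class scenarios
span a balanced accurate classifier, a dominant accurate class, and a
dominant class with poor recall.

Replicates where an estimator is undefined (an empty class for maF1, a
zero margin for maF1*) are data, not errors: the ``undefined_policy``
controls whether they are dropped from the coverage denominator
(default) or counted as non-covering.

The per-replicate estimates and variances are computed with vectorized
closed forms; a test pins them to the scalar :mod:`f1ci.delta_ci` path.
"""

from __future__ import annotations

import dataclasses
import zlib
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .confusion_io import ConfusionCounts, ProbabilityTable
from .errors import InputError
from .point_metrics import macro_f1, macro_f1_star, micro_f1

__all__ = [
    "ScenarioSpec",
    "CoverageResult",
    "builtin_scenarios",
    "scenario_by_name",
    "simulate_tables",
    "batch_estimates",
    "coverage_study",
    "coverage_table",
    "DEFAULT_N_GRID",
]

DEFAULT_N_GRID = (25, 50, 100, 500, 1000, 5000)
_MEASURES = ("miF1", "maF1", "maF1star")


@dataclasses.dataclass(frozen=True)
class ScenarioSpec:
    """A named true probability table with its analytic F1 scores."""

    name: str
    p_true: ProbabilityTable
    true_scores: dict

    @classmethod
    def from_table(cls, name: str, pt: ProbabilityTable) -> "ScenarioSpec":
        scores = {
            "miF1": micro_f1(pt),
            "maF1": macro_f1(pt),
            "maF1star": macro_f1_star(pt)[0],
        }
        return cls(name, pt, scores)


@dataclasses.dataclass(frozen=True)
class CoverageResult:
    """Empirical coverage of one (scenario, n, measure) cell."""

    scenario: str
    n: int
    measure: str
    alpha: float
    reps_requested: int
    reps_evaluable: int
    reps_covering: int
    coverage: float
    undefined_policy: str
    seed: int
    mc_standard_error: float


def _fraction_table(cells, denom: int) -> ProbabilityTable:
    p = np.array([[Fraction(c, denom) for c in row] for row in cells], dtype=float)
    return ProbabilityTable(p)


def builtin_scenarios() -> list[ScenarioSpec]:
    """The three built-in 3-class simulation scenarios.

    1. balanced: diagonal 8/30, off-diagonal 1/30 (all scores 0.80);
    2. one dominant, well-classified class (miF1 0.72 > maF1 0.50);
    3. one dominant class with high precision but poor recall
       (miF1 0.48, maF1 0.44, maF1* 0.55).
    """
    s1 = _fraction_table([[8, 1, 1], [1, 8, 1], [1, 1, 8]], 30)
    s2 = _fraction_table([[64, 3, 3], [8, 4, 3], [8, 3, 4]], 100)
    s3 = _fraction_table([[32, 1, 1], [24, 8, 1], [24, 1, 8]], 100)
    return [
        ScenarioSpec.from_table("scenario1", s1),
        ScenarioSpec.from_table("scenario2", s2),
        ScenarioSpec.from_table("scenario3", s3),
    ]


def scenario_by_name(name: str) -> ScenarioSpec:
    """Look up a built-in scenario by name or 1-based number."""
    scenarios = {s.name: s for s in builtin_scenarios()}
    key = f"scenario{name}" if str(name) in ("1", "2", "3") else str(name)
    if key not in scenarios:
        raise InputError(
            f"unknown scenario {name!r}; built-ins are 1, 2, 3"
        )
    return scenarios[key]


def _cell_rng(seed: int, scenario: str, n: int) -> np.random.Generator:
    """Independent, individually reproducible substream per (scenario, n)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(scenario.encode()), int(n)])
    )


def simulate_tables(
    p_true: ProbabilityTable, n: int, reps: int, seed=None
) -> np.ndarray:
    """Draw ``reps`` confusion matrices ~ Multinomial(n; p_true).

    Returns an integer array of shape (reps, r, r); identical seed gives
    an identical stream.  ``seed`` may be an int or a Generator.
    """
    if reps < 1:
        raise InputError(f"reps must be >= 1, got {reps}")
    if n < 1:
        raise InputError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = p_true.r
    flat = rng.multinomial(n, p_true.p.ravel(), size=reps)
    return flat.reshape(reps, r, r)


def iter_tables(p_true: ProbabilityTable, n: int, reps: int, seed=None):
    """Yield the same draws as :func:`simulate_tables` as ConfusionCounts."""
    for tab in simulate_tables(p_true, n, reps, seed):
        yield ConfusionCounts(tab, p_true.class_labels)


def batch_estimates(tables: np.ndarray, n: int) -> dict:
    """Vectorized plug-in estimates and delta-method variances.

    ``tables`` has shape (m, r, r).  Returns, per measure, arrays
    ``estimate`` and ``variance`` of length m; replicates where the
    estimator is undefined hold NaN in both.
    """
    tables = np.asarray(tables, dtype=np.float64)
    m, r, _ = tables.shape
    p = tables / n
    d = np.diagonal(p, axis1=1, axis2=2)  # (m, r)
    rm = p.sum(axis=2)
    cm = p.sum(axis=1)
    out = {}

    # miF1: trace, variance T(1-T)/n
    t = d.sum(axis=1)
    out["miF1"] = {"estimate": t, "variance": t * (1.0 - t) / n}

    eye = np.eye(r, dtype=bool)

    # maF1: mean of 2 p_ii / s_i with s_i = p_i. + p_.i
    s = rm + cm
    ok = (s > 0).all(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = 2.0 * d / s
        est = f1.mean(axis=1)
        a = d / s**2
        grad = -(2.0 / r) * (a[:, :, None] + a[:, None, :])
        grad[:, eye] += (2.0 / r) / s
        var = _qform(grad, p) / n
    est[~ok] = np.nan
    var[~ok] = np.nan
    out["maF1"] = {"estimate": est, "variance": var}

    # maF1*: harmonic mean of maP, maR
    ok = (rm > 0).all(axis=1) & (cm > 0).all(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ma_p = (d / rm).mean(axis=1)
        ma_r = (d / cm).mean(axis=1)
        tot = ma_p + ma_r
        est = np.where(tot > 0, 2.0 * ma_p * ma_r / tot, 0.0)
        h_p = np.where(tot > 0, 2.0 * ma_r**2 / tot**2, 0.0)
        h_r = np.where(tot > 0, 2.0 * ma_p**2 / tot**2, 0.0)
        gp = np.broadcast_to(
            (-(1.0 / r) * d / rm**2)[:, :, None], (m, r, r)
        ).copy()
        gp[:, eye] += (1.0 / r) / rm
        gr = np.broadcast_to(
            (-(1.0 / r) * d / cm**2)[:, None, :], (m, r, r)
        ).copy()
        gr[:, eye] += (1.0 / r) / cm
        grad = h_p[:, None, None] * gp + h_r[:, None, None] * gr
        var = _qform(grad, p) / n
    est = np.where(ok, est, np.nan)
    var = np.where(ok, var, np.nan)
    out["maF1star"] = {"estimate": est, "variance": var}
    return out


def _qform(grad: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Batched g^T (diag(p) - p p^T) g over the last two axes."""
    gp = np.sum(grad * p, axis=(1, 2))
    return np.sum(grad * grad * p, axis=(1, 2)) - gp * gp


def coverage_study(
    scenario: ScenarioSpec,
    n: int,
    reps: int = 100_000,
    alpha: float = 0.05,
    measures=_MEASURES,
    undefined_policy: str = "drop",
    seed: int = 0,
    batch: int = 200_000,
) -> dict[str, CoverageResult]:
    """Empirical coverage of the Wald intervals under one scenario.

    For each replicate the (1 - alpha) interval for each measure is
    checked for containment (closed interval) of the scenario's analytic
    true score.  Undefined replicates are excluded from the denominator
    (``undefined_policy="drop"``) or counted as misses (``"noncover"``).
    """
    if undefined_policy not in ("drop", "noncover"):
        raise InputError(f"unknown undefined_policy {undefined_policy!r}")
    if not 0.0 < alpha < 1.0:
        raise InputError(f"alpha must be in (0, 1), got {alpha}")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    rng = _cell_rng(seed, scenario.name, n)
    evaluable = {mname: 0 for mname in measures}
    covering = {mname: 0 for mname in measures}
    done = 0
    while done < reps:
        chunk = min(batch, reps - done)
        tables = simulate_tables(scenario.p_true, n, chunk, rng)
        ests = batch_estimates(tables, n)
        for mname in measures:
            est = ests[mname]["estimate"]
            var = ests[mname]["variance"]
            ok = np.isfinite(est)
            se = np.sqrt(var[ok])
            true = scenario.true_scores[mname]
            hit = (est[ok] - z * se <= true) & (true <= est[ok] + z * se)
            evaluable[mname] += int(ok.sum())
            covering[mname] += int(hit.sum())
        done += chunk

    results = {}
    for mname in measures:
        denom = evaluable[mname] if undefined_policy == "drop" else reps
        cov = covering[mname] / denom if denom else float("nan")
        mc_se = float(np.sqrt(cov * (1.0 - cov) / denom)) if denom else float("nan")
        results[mname] = CoverageResult(
            scenario=scenario.name,
            n=n,
            measure=mname,
            alpha=alpha,
            reps_requested=reps,
            reps_evaluable=evaluable[mname],
            reps_covering=covering[mname],
            coverage=cov,
            undefined_policy=undefined_policy,
            seed=seed,
            mc_standard_error=mc_se,
        )
    return results


def coverage_table(
    scenarios=None,
    n_grid=DEFAULT_N_GRID,
    reps: int = 100_000,
    alpha: float = 0.05,
    undefined_policy: str = "drop",
    seed: int = 0,
) -> pd.DataFrame:
    """Coverage grid: rows n, one column per (scenario, measure).

    Each cell is computed from its own seed substream, so any single cell
    can be reproduced without rerunning the grid.
    """
    if scenarios is None:
        scenarios = builtin_scenarios()
    rows = []
    for n in n_grid:
        row = {"n": n}
        for sc in scenarios:
            res = coverage_study(
                sc, n, reps=reps, alpha=alpha,
                undefined_policy=undefined_policy, seed=seed,
            )
            for mname in _MEASURES:
                row[f"{sc.name}:{mname}"] = res[mname].coverage
        rows.append(row)
    return pd.DataFrame(rows).set_index("n")
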