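"""Model-independent exponential CDF analysis.

Single/double exponential fits to empirical dwell CDFs with amplitudes
constrained to sum to one, F-test profile confidence intervals, an F-test
for one-vs-two phases, a runs test on residual signs, and decomposition of
apparent rates versus ligand concentration into bimolecular slopes and
concentration-independent means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import brentq, least_squares

from .dwells import EmpiricalCDF

__all__ = [
    "ExpFitResult",
    "ConcentrationSeries",
    "fit_exp_cdf",
    "ftest_ci",
    "ftest_compare",
    "runs_test",
    "concentration_decomposition",
]


@dataclass
class ExpFitResult:
    """Exponential-mixture CDF fit: ``CDF(t) = 1 - sum_i A_i exp(-k_i t)``.

    Rates are sorted descending with matching amplitudes; amplitudes sum
    to 1. ``chi2`` is the plain sum of squared residuals.
    """

    n_phases: int
    rates: np.ndarray
    amplitudes: np.ndarray
    residuals: np.ndarray
    chi2: float
    times: np.ndarray
    values: np.ndarray
    success: bool
    degenerate: bool = False
    ci: dict[str, tuple[float, float]] | None = None
    ci_flags: dict[str, str] | None = None
    ci_level: float | None = None

    @property
    def n_points(self) -> int:
        return len(self.times)

    @property
    def n_free(self) -> int:
        return 2 * self.n_phases - 1

    def param_dict(self) -> dict[str, float]:
        d = {f"k{i + 1}": float(k) for i, k in enumerate(self.rates)}
        for i, a in enumerate(self.amplitudes[:-1]):
            d[f"A{i + 1}"] = float(a)
        return d

    def model(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return 1.0 - np.sum(
            self.amplitudes[:, None] * np.exp(-np.outer(self.rates, t)), axis=0
        )


def _exp_model(theta: np.ndarray, n_phases: int, t: np.ndarray) -> np.ndarray:
    if n_phases == 1:
        return 1.0 - np.exp(-theta[0] * t)
    k1, k2, a1 = theta
    return 1.0 - a1 * np.exp(-k1 * t) - (1.0 - a1) * np.exp(-k2 * t)


def fit_exp_cdf(cdf: EmpiricalCDF, n_phases: int = 1) -> ExpFitResult:
    """Least-squares exponential-mixture fit on the CDF grid.

    A two-phase fit whose rates collapse onto each other is flagged
    degenerate and the single-phase result is returned in its place.
    """
    if n_phases not in (1, 2):
        raise ValueError("n_phases must be 1 or 2")
    t, y = cdf.times, cdf.values
    n_free = 2 * n_phases - 1
    if len(t) < 5 * n_free:
        raise ValueError(f"need at least {5 * n_free} grid points for {n_phases} phase(s)")

    # moment-style initial guess from the median crossing
    idx = np.searchsorted(y, 0.5)
    t_half = t[min(idx, len(t) - 1)]
    k0 = np.log(2.0) / max(t_half, t[0])

    if n_phases == 1:
        theta0 = np.array([k0])
        lb, ub = [1e-9], [1e6]
    else:
        theta0 = np.array([3.0 * k0, 0.3 * k0, 0.5])
        lb, ub = [1e-9, 1e-9, 0.0], [1e6, 1e6, 1.0]

    def residual(theta):
        return _exp_model(theta, n_phases, t) - y

    sol = least_squares(residual, theta0, bounds=(lb, ub), method="trf",
                        ftol=1e-12, xtol=1e-12, gtol=1e-12, x_scale="jac")
    theta = sol.x
    if n_phases == 1:
        rates = np.array([theta[0]])
        amps = np.array([1.0])
    else:
        rates = theta[:2]
        amps = np.array([theta[2], 1.0 - theta[2]])
        order = np.argsort(rates)[::-1]
        rates, amps = rates[order], amps[order]
        rel_gap = abs(rates[0] - rates[1]) / max(rates[0], 1e-12)
        if rel_gap < 1e-3 or amps.min() < 1e-6:
            single = fit_exp_cdf(cdf, n_phases=1)
            single.degenerate = True
            warnings.warn("two-phase fit degenerate; returning single-phase fallback",
                          stacklevel=2)
            return single

    res = _exp_model(theta, n_phases, t) - y
    return ExpFitResult(
        n_phases=n_phases,
        rates=rates,
        amplitudes=amps,
        residuals=res,
        chi2=float(np.sum(res ** 2)),
        times=t,
        values=y,
        success=bool(sol.success),
    )


def _refit_fixed(
    fit: ExpFitResult, fixed_index: int, fixed_value: float
) -> float:
    """Best SSR with one parameter pinned; others re-optimized."""
    t, y = fit.times, fit.values
    n_phases = fit.n_phases
    # full parameter vector in (k..., A1) layout
    if n_phases == 1:
        full = np.array([fit.rates[0]])
        lb, ub = np.array([1e-9]), np.array([1e6])
    else:
        full = np.array([fit.rates[0], fit.rates[1], fit.amplitudes[0]])
        lb, ub = np.array([1e-9, 1e-9, 0.0]), np.array([1e6, 1e6, 1.0])
    free = [i for i in range(len(full)) if i != fixed_index]
    if not free:
        theta = full.copy()
        theta[fixed_index] = fixed_value
        return float(np.sum((_exp_model(theta, n_phases, t) - y) ** 2))

    def residual(sub):
        theta = full.copy()
        theta[fixed_index] = fixed_value
        theta[free] = sub
        return _exp_model(theta, n_phases, t) - y

    sol = least_squares(residual, full[free], bounds=(lb[free], ub[free]),
                        method="trf", ftol=1e-12, xtol=1e-12)
    return float(2.0 * sol.cost)


def ftest_ci(fit: ExpFitResult, level: float = 0.68,
             expand_limit: float = 1e4) -> ExpFitResult:
    """Profile (F-test) confidence intervals for every free parameter.

    A fixed parameter value is inside the interval while
    ``F = (chi2_fixed / chi2_best - 1) * (N - P) <= F_crit(level; 1, N-P)``.
    Bounds are bracketed geometrically and refined by root finding; a profile
    still inside the acceptance region at the search limit is reported at
    that limit and flagged.
    """
    dof = fit.n_points - fit.n_free
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    if not fit.success:
        raise ValueError("cannot profile a non-converged fit")
    f_crit = stats.f.ppf(level, 1, dof)
    chi2_best = max(fit.chi2, 1e-300)

    names = list(fit.param_dict())
    if fit.n_phases == 1:
        centers = [fit.rates[0]]
        boxes = [(1e-9, 1e6)]
    else:
        centers = [fit.rates[0], fit.rates[1], fit.amplitudes[0]]
        boxes = [(1e-9, 1e6), (1e-9, 1e6), (0.0, 1.0)]

    def excess(i, value):
        chi2 = _refit_fixed(fit, i, value)
        return (chi2 / chi2_best - 1.0) * dof - f_crit

    ci: dict[str, tuple[float, float]] = {}
    flags: dict[str, str] = {}
    for i, (name, center, (blo, bhi)) in enumerate(zip(names, centers, boxes)):
        bounds = []
        flag = ""
        for direction in (-1, +1):
            inner = center
            step = max(abs(center), 1e-6) * 0.05
            outer = None
            for _ in range(200):
                cand = inner + direction * step
                cand = min(max(cand, blo), bhi)
                if excess(i, cand) > 0:
                    outer = cand
                    break
                inner = cand
                step *= 1.6
                if cand in (blo, bhi) or step > expand_limit * max(abs(center), 1e-6):
                    break
            if outer is None:
                bounds.append(inner)
                flag = "open"
            else:
                a, b = sorted((inner, outer))
                if a == b:
                    bounds.append(a)
                else:
                    bounds.append(brentq(lambda v: excess(i, v), a, b, xtol=1e-10))
        lo, hi = sorted(bounds)
        ci[name] = (float(lo), float(hi))
        if flag:
            flags[name] = flag
    fit.ci = ci
    fit.ci_flags = flags
    fit.ci_level = level
    return fit


def ftest_compare(single: ExpFitResult, double: ExpFitResult) -> tuple[float, float]:
    """Extra-sum-of-squares F-test for two phases over one.

    Returns ``(F, p)``; small ``p`` means the second phase is justified.
    """
    if double.n_phases != 2 or single.n_phases != 1:
        raise ValueError("expected a single- and a double-exponential fit")
    n = single.n_points
    dp = double.n_free - single.n_free
    dof = n - double.n_free
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    num = (single.chi2 - double.chi2) / dp
    den = double.chi2 / dof
    if den <= 0:
        return np.inf, 0.0
    f = num / den
    return float(f), float(stats.f.sf(f, dp, dof))


def runs_test(residuals: np.ndarray) -> tuple[float, float]:
    """Wald-Wolfowitz runs test on residual signs.

    Returns ``(z, p)``; a small ``p`` indicates non-random (structured)
    residuals. Zeros are dropped.
    """
    signs = np.sign(residuals)
    signs = signs[signs != 0]
    n = len(signs)
    n_pos = int(np.sum(signs > 0))
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        return 0.0, 1.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    mu = 2.0 * n_pos * n_neg / n + 1.0
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n ** 2 * (n - 1.0))
    if var <= 0:
        return 0.0, 1.0
    z = (runs - mu) / np.sqrt(var)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class ConcentrationSeries:
    """Apparent rates of one phase across ligand concentrations."""

    concentrations: np.ndarray
    rates: np.ndarray
    rate_errors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.concentrations.shape != self.rates.shape:
            raise ValueError("concentrations and rates must have equal length")
        if self.rate_errors is not None:
            self.rate_errors = np.asarray(self.rate_errors, dtype=float)
            if self.rate_errors.shape != self.rates.shape:
                raise ValueError("rate_errors length mismatch")


def concentration_decomposition(
    series: ConcentrationSeries,
    alpha: float = 0.05,
    force: str | None = None,
) -> dict:
    """Classify a phase as ligand-dependent or flat and summarize it.

    Dependent phases (slope t-test ``p < alpha``, overridable via ``force``)
    get a least-squares line whose slope is the bimolecular constant
    (nM^-1 s^-1); flat phases get the arithmetic mean rate. Weighted
    regression is used when per-point errors are supplied.
    """
    c, k = series.concentrations, series.rates
    if force not in (None, "dependent", "flat"):
        raise ValueError("force must be None, 'dependent' or 'flat'")
    if force == "flat":
        return {"kind": "flat", "mean_rate": float(np.mean(k)), "n": len(k)}
    if len(c) < 2:
        if force == "dependent":
            raise ValueError("need >= 2 concentrations for a slope")
        return {"kind": "flat", "mean_rate": float(np.mean(k)), "n": len(k)}

    if series.rate_errors is not None and np.all(series.rate_errors > 0):
        w = 1.0 / series.rate_errors ** 2
    else:
        w = np.ones_like(k)
    wsum = w.sum()
    cbar = np.sum(w * c) / wsum
    kbar = np.sum(w * k) / wsum
    sxx = np.sum(w * (c - cbar) ** 2)
    if sxx == 0:
        raise ValueError("concentrations are all identical; slope undefined")
    slope = np.sum(w * (c - cbar) * (k - kbar)) / sxx
    intercept = kbar - slope * cbar

    dependent = force == "dependent"
    p_slope = np.nan
    if force is None:
        dof = len(c) - 2
        if dof > 0:
            resid = k - (intercept + slope * c)
            s2 = np.sum(w * resid ** 2) / dof
            se = np.sqrt(s2 / sxx)
            if se == 0:
                dependent = abs(slope) > 0
                p_slope = 0.0 if dependent else 1.0
            else:
                t_stat = slope / se
                p_slope = float(2.0 * stats.t.sf(abs(t_stat), dof))
                dependent = p_slope < alpha
        else:
            # 2 points fit a line exactly; classify by relative spread
            dependent = abs(k[-1] - k[0]) > 0.05 * max(abs(k).max(), 1e-12)

    if dependent:
        return {
            "kind": "dependent",
            "bimolecular_slope": float(slope),
            "intercept": float(intercept),
            "p_slope": p_slope,
            "n": len(k),
        }
    return {"kind": "flat", "mean_rate": float(np.mean(k)), "p_slope": p_slope, "n": len(k)}
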