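"""Optimum-curve growth kinetics: Michaelis–Menten with linear inhibition.

Phytoplankton growth rate as a function of dissolved CO2 (μmol kg⁻¹) is
modelled with a modified Michaelis–Menten form,

    V(c) = X·c / (Y + c) − S·c            (inhibited form, "eq1")

where the linear −S·c term captures the decline in growth at
supra-saturating CO2 (equivalently elevated H⁺, with which CO2 is tightly
correlated in seawater). With S = 0 the model is the standard saturating
Michaelis–Menten form ("eq2"), V(c) = Vmax·c / (K½ + c).

The raw fit parameters (X, Y, S) are converted to ecologically meaningful
quantities: the optimum concentration C_opt = √(X·Y/S) − Y (the stationary
point of V), the maximum rate Vmax = V(C_opt), and the half-saturation
constant K½, defined as the concentration on the ascending limb at which
V = Vmax/2 (this reduces to K½ = Y exactly when S = 0).

:class:`GrowthKineticsModel` is a scikit-learn-compatible regressor
(``fit``/``predict``/``get_params``), so it composes with sklearn model
selection; :func:`fit_growth_model` and friends are thin functional
wrappers returning a :class:`FitResult` record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares, root

try:  # sklearn integration is optional at import time
    from sklearn.base import BaseEstimator, RegressorMixin
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore
        pass

    class RegressorMixin:  # type: ignore
        pass

__all__ = [
    "KineticParams",
    "DerivedKinetics",
    "FitResult",
    "GrowthKineticsModel",
    "eq1_rate",
    "eq2_rate",
    "derive_kinetics",
    "params_from_derived",
    "fit_growth_model",
    "bootstrap_ci",
    "select_model",
]


@dataclass(frozen=True)
class KineticParams:
    """Raw parameters of the inhibited Michaelis–Menten form.

    ``X`` (d⁻¹) and ``Y`` (μmol kg⁻¹) are the saturating-limb parameters;
    ``S`` (d⁻¹ per μmol kg⁻¹, ≥ 0) is the linear inhibition coefficient
    (S = 0 recovers the standard form, where X = Vmax and Y = K½).
    """

    X: float
    Y: float
    S: float = 0.0

    def __post_init__(self):
        if self.X <= 0 or self.Y <= 0:
            raise ValueError(f"X and Y must be positive, got X={self.X}, Y={self.Y}")
        if self.S < 0:
            raise ValueError(f"S must be non-negative, got S={self.S}")


@dataclass(frozen=True)
class DerivedKinetics:
    """Reported kinetic quantities derived from :class:`KineticParams`.

    ``c_opt`` is NaN (with ``has_optimum=False``) for the saturating S = 0
    form, which has no interior maximum.
    """

    vmax: float  # d⁻¹
    k_half: float  # μmol kg⁻¹
    c_opt: float  # μmol kg⁻¹ (NaN when S == 0)
    has_optimum: bool


@dataclass
class FitResult:
    """A fitted growth model with derived kinetics and bootstrap CIs."""

    params: KineticParams
    derived: DerivedKinetics
    r_squared: float
    n_points: int
    model_id: str  # "eq1" | "eq2"
    s_at_boundary: bool = False
    ci: dict = field(default_factory=dict)  # quantity -> (lo, hi)
    bootstrap_draws: np.ndarray | None = None  # (n_kept, 3) X, Y, S
    n_boot_failed: int = 0
    boot_mode: str | None = None
    seed: int | None = None

    def rate(self, c):
        return eq1_rate(c, self.params)


def eq1_rate(c, params: KineticParams):
    """Growth rate V(c) = X·c/(Y+c) − S·c at CO2 ``c`` (μmol kg⁻¹).

    Accepts scalars or arrays; negative ``c`` raises.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("CO2 concentrations must be non-negative")
    out = params.X * c / (params.Y + c) - params.S * c
    return float(out) if out.ndim == 0 else out


def eq2_rate(c, params: KineticParams):
    """Standard Michaelis–Menten rate (the S = 0 special case)."""
    return eq1_rate(c, KineticParams(params.X, params.Y, 0.0))


def derive_kinetics(params: KineticParams) -> DerivedKinetics:
    """Convert raw (X, Y, S) to (Vmax, K½, C_opt).

    For S > 0 the stationary point is C_opt = √(X·Y/S) − Y, which is an
    interior maximum only when X > S·Y; K½ is found by bracketed
    root-finding for V(c) = Vmax/2 on the ascending limb (0, C_opt).
    For S = 0, Vmax = X and K½ = Y exactly.
    """
    X, Y, S = params.X, params.Y, params.S
    if S == 0.0:
        return DerivedKinetics(vmax=X, k_half=Y, c_opt=math.nan, has_optimum=False)
    if X * Y / S <= Y * Y:
        raise ValueError(
            f"monotone curve: no interior maximum for X={X}, Y={Y}, S={S} "
            "(requires X > S·Y)"
        )
    c_opt = math.sqrt(X * Y / S) - Y
    vmax = float(eq1_rate(c_opt, params))
    k_half = brentq(
        lambda c: eq1_rate(c, params) - vmax / 2.0, 1e-12 * c_opt, c_opt,
        xtol=1e-14, rtol=8.9e-16,
    )
    return DerivedKinetics(vmax=vmax, k_half=float(k_half), c_opt=c_opt,
                           has_optimum=True)


def params_from_derived(vmax: float, k_half: float, s: float) -> KineticParams:
    """Invert (Vmax, K½, S) to raw (X, Y, S) — used to build species profiles
    from reported kinetic quantities."""
    if s == 0.0:
        return KineticParams(X=vmax, Y=k_half, S=0.0)

    def f(p):
        X, Y = p
        if X <= s * Y or X <= 0 or Y <= 0:
            return [1e3, 1e3]
        d = derive_kinetics(KineticParams(X, Y, s))
        return [d.vmax - vmax, d.k_half - k_half]

    sol = root(f, x0=[vmax * 1.3, k_half * 1.3], method="hybr", tol=1e-12)
    if not sol.success:
        raise RuntimeError(f"could not invert derived kinetics: {sol.message}")
    return KineticParams(X=float(sol.x[0]), Y=float(sol.x[1]), S=s)


# ----------------------------------------------------------------- fitting


def _residuals_eq1(theta, c, y):
    X, Y, S = theta
    return X * c / (Y + c) - S * c - y


def _jac_eq1(theta, c, y):
    X, Y, _ = theta
    J = np.empty((c.size, 3))
    J[:, 0] = c / (Y + c)
    J[:, 1] = -X * c / (Y + c) ** 2
    J[:, 2] = -c
    return J


def _residuals_eq2(theta, c, y):
    X, Y = theta
    return X * c / (Y + c) - y


def _jac_eq2(theta, c, y):
    X, Y = theta
    J = np.empty((c.size, 2))
    J[:, 0] = c / (Y + c)
    J[:, 1] = -X * c / (Y + c) ** 2
    return J


def _initial_guess(c, y):
    """Heuristic start: X from the max rate, Y from the concentration nearest
    half the max rate, S from the terminal slope if negative."""
    ymax = float(np.max(y))
    X0 = max(ymax, 1e-3)
    half = ymax / 2.0
    Y0 = float(c[np.argmin(np.abs(y - half))])
    Y0 = max(Y0, 1e-3)
    order = np.argsort(c)
    ch, yh = c[order][-2:], y[order][-2:]
    S0 = 0.0
    if ch[1] > ch[0]:
        slope = (yh[1] - yh[0]) / (ch[1] - ch[0])
        if slope < 0:
            S0 = -slope
    return X0, Y0, max(S0, 1e-6)


def _ls_fit(c, y, model_id, theta0):
    """One least-squares solve (Levenberg–Marquardt, analytic Jacobian)."""
    if model_id == "eq1":
        res = least_squares(_residuals_eq1, theta0, jac=_jac_eq1, args=(c, y),
                            method="lm", xtol=1e-12, ftol=1e-12, gtol=1e-12)
    else:
        res = least_squares(_residuals_eq2, theta0, jac=_jac_eq2, args=(c, y),
                            method="lm", xtol=1e-12, ftol=1e-12, gtol=1e-12)
    return res


def _fit_point(c, y, model_id, seed=0, n_starts=5, theta0=None):
    """Multi-start LM fit; returns (theta, sse, s_at_boundary) with S ≥ 0 and
    Y > 0 enforced by clamping/refit. ``theta0`` skips the multi-start."""
    best = None
    if theta0 is not None:
        starts = [np.asarray(theta0, dtype=float)]
    else:
        X0, Y0, S0 = _initial_guess(c, y)
        base = [X0, Y0, S0] if model_id == "eq1" else [X0, Y0]
        rng = np.random.default_rng(seed)
        starts = [np.asarray(base)]
        for _ in range(n_starts - 1):
            jitter = rng.uniform(0.4, 2.5, size=len(base))
            starts.append(np.asarray(base) * jitter)
    for th0 in starts:
        try:
            res = _ls_fit(c, y, model_id, th0)
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)) or res.x[1] <= 0 or res.x[0] <= 0:
            continue
        sse = float(2.0 * res.cost)
        if best is None or sse < best[1] - 1e-14:
            best = (res.x, sse)
    if best is None:
        raise RuntimeError(
            f"growth-model fit did not converge ({model_id}, n={c.size}, "
            f"CO2 range [{c.min():.3g}, {c.max():.3g}])"
        )
    theta, sse = best
    s_at_boundary = False
    if model_id == "eq1" and theta[2] < 0:
        # negative inhibition is not allowed: clamp to the S=0 boundary
        res2 = _ls_fit(c, y, "eq2", theta[:2])
        theta = np.array([res2.x[0], res2.x[1], 0.0])
        sse = float(2.0 * res2.cost)
        s_at_boundary = True
    return theta, sse, s_at_boundary


def _as_points(points):
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (CO2, rate)")
    c, y = pts[:, 0], pts[:, 1]
    if np.any(c < 0):
        raise ValueError("CO2 values must be non-negative")
    if np.allclose(c, c[0]):
        raise ValueError("CO2 values must not all be equal")
    return c, y


class GrowthKineticsModel(BaseEstimator, RegressorMixin):
    """Scikit-learn-style regressor for the CO2 → growth-rate optimum curve.

    Parameters
    ----------
    model : {"eq1", "eq2"}
        "eq1" fits the inhibited form (3 parameters, S ≥ 0); "eq2" the
        standard saturating form (2 parameters).
    n_starts : int
        Number of deterministic jittered restarts for the multi-start
        least-squares solve.
    seed : int
        Seed for the (deterministic) start jitter.

    Attributes
    ----------
    params_ : KineticParams
    derived_ : DerivedKinetics
    r_squared_ : float
    s_at_boundary_ : bool
        True when an eq1 fit hit the S = 0 boundary (saturating data).
    n_points_ : int

    Examples
    --------
    >>> import numpy as np
    >>> c = np.linspace(0.5, 100, 12)
    >>> true = KineticParams(1.5, 5.0, 0.005)
    >>> m = GrowthKineticsModel(model="eq1").fit(c, eq1_rate(c, true))
    >>> round(m.derived_.vmax, 3)
    1.138
    """

    def __init__(self, model: str = "eq1", n_starts: int = 5, seed: int = 0):
        self.model = model
        self.n_starts = n_starts
        self.seed = seed

    def fit(self, X, y):
        if self.model not in ("eq1", "eq2"):
            raise ValueError(f"model must be 'eq1' or 'eq2', got {self.model!r}")
        c = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if c.size != y.size:
            raise ValueError("X and y must have the same length")
        n_par = 3 if self.model == "eq1" else 2
        min_n = 4 if self.model == "eq1" else 3
        if c.size < min_n:
            raise ValueError(
                f"need at least {min_n} points for {self.model}, got {c.size}"
            )
        _ = _as_points(np.column_stack([c, y]))
        theta, sse, s_bound = _fit_point(c, y, self.model, seed=self.seed,
                                         n_starts=self.n_starts)
        if self.model == "eq1":
            self.params_ = KineticParams(*theta)
        else:
            self.params_ = KineticParams(theta[0], theta[1], 0.0)
        self.derived_ = derive_kinetics(self.params_)
        sstot = float(np.sum((y - y.mean()) ** 2))
        self.r_squared_ = 1.0 - sse / sstot if sstot > 0 else 1.0
        self.s_at_boundary_ = s_bound
        self.n_points_ = int(c.size)
        self._c, self._y = c, y
        return self

    def predict(self, X):
        c = np.asarray(X, dtype=float).reshape(-1)
        return eq1_rate(c, self.params_)

    def result(self) -> FitResult:
        """Package the fitted state as a :class:`FitResult` record."""
        return FitResult(
            params=self.params_,
            derived=self.derived_,
            r_squared=self.r_squared_,
            n_points=self.n_points_,
            model_id=self.model,
            s_at_boundary=self.s_at_boundary_,
            seed=self.seed,
        )


def fit_growth_model(points, model_id: str = "eq1", seed: int = 0) -> FitResult:
    """Fit the growth model to (CO2, rate) ``points``; functional wrapper
    around :class:`GrowthKineticsModel`."""
    c, y = _as_points(points)
    m = GrowthKineticsModel(model=model_id, seed=seed).fit(c, y)
    return m.result()


def _boot_quantities(theta):
    """(X, Y, S) -> (X, Y, S, Vmax, K_half, C_opt) for one replicate."""
    X, Y, S = theta
    try:
        d = derive_kinetics(KineticParams(X, Y, max(S, 0.0)))
    except ValueError:  # monotone replicate: saturating summary
        return X, Y, S, X, Y, math.nan
    return X, Y, S, d.vmax, d.k_half, d.c_opt


_CI_NAMES = ("X", "Y", "S", "vmax", "k_half", "c_opt")


def bootstrap_ci(points, fit: FitResult, n_reps: int = 1000,
                 mode: str = "nonparametric", seed: int = 0,
                 alpha: float = 0.05) -> FitResult:
    """Percentile bootstrap confidence intervals for the fitted quantities.

    ``nonparametric`` resamples the (CO2, rate) points with replacement;
    ``parametric`` resamples residuals onto the fitted values. Each
    replicate is refit from the point estimate (warm start). Replicates
    that fail to converge are dropped and counted; more than 50% failures
    is an error.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be at least 100")
    if mode not in ("nonparametric", "parametric"):
        raise ValueError(f"unknown bootstrap mode {mode!r}")
    c, y = _as_points(points)
    rng = np.random.default_rng(seed)
    theta_hat = np.array([fit.params.X, fit.params.Y, fit.params.S])
    model_id = fit.model_id
    if model_id == "eq2":
        theta_hat = theta_hat[:2]
    yhat = eq1_rate(c, fit.params)
    resid = y - yhat
    n = c.size

    draws = np.empty((n_reps, 3))
    kept = 0
    failed = 0
    for _ in range(n_reps):
        if mode == "nonparametric":
            idx = rng.integers(0, n, size=n)
            cb, yb = c[idx], y[idx]
            if np.allclose(cb, cb[0]):
                failed += 1
                continue
        else:
            cb = c
            yb = yhat + rng.choice(resid, size=n, replace=True)
        try:
            theta, _, _ = _fit_point(cb, yb, model_id, theta0=theta_hat)
        except Exception:
            failed += 1
            continue
        if model_id == "eq2":
            theta = np.array([theta[0], theta[1], 0.0])
        draws[kept] = theta
        kept += 1
    if failed > n_reps / 2:
        raise RuntimeError(
            f"bootstrap failed: {failed}/{n_reps} replicates did not converge"
        )
    draws = draws[:kept]
    qs = np.array([_boot_quantities(t) for t in draws])
    lo, hi = 100 * alpha / 2.0, 100 * (1.0 - alpha / 2.0)
    ci = {}
    for j, name in enumerate(_CI_NAMES):
        col = qs[:, j]
        col = col[np.isfinite(col)]
        if col.size:
            ci[name] = (float(np.percentile(col, lo)),
                        float(np.percentile(col, hi)))
    fit.ci = ci
    fit.bootstrap_draws = draws
    fit.n_boot_failed = failed
    fit.boot_mode = mode
    fit.seed = seed
    return fit


def select_model(points, seed: int = 0, n_reps: int = 200) -> str:
    """Choose between the inhibited and saturating forms.

    Fits both; returns "eq1" when the bootstrap CI of the inhibition
    coefficient S excludes 0 (a decline in growth is evident), else "eq2".
    """
    c, y = _as_points(points)
    if c.size < 4:
        raise ValueError("model selection needs at least 4 points")
    fit1 = fit_growth_model(points, "eq1", seed=seed)
    if fit1.s_at_boundary:
        return "eq2"
    fit1 = bootstrap_ci(points, fit1, n_reps=max(n_reps, 100), seed=seed)
    lo, hi = fit1.ci["S"]
    return "eq1" if lo > 0.0 else "eq2"
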