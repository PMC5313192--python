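"""Maximum-likelihood growth from tagging increments (Francis reparameterization).

The von Bertalanffy growth function is reparameterized in terms of the mean
annual growth increments ``g_alpha`` and ``g_beta`` at two fixed reference
lengths ``alpha < beta`` chosen inside the observed length range.  For a
shark released at length ``l1`` and at large for ``dt`` years the expected
increment is

    mu = (L_inf - l1) * (1 - exp(-k * dt))

with

    L_inf = (beta * g_alpha - alpha * g_beta) / (g_alpha - g_beta)
    k     = -ln(1 + (g_alpha - g_beta) / (alpha - beta))

Observed increments are modelled as a contaminated normal: with probability
``1 - p`` the increment is Normal(mu + m, sqrt((nu*mu)^2 + s^2)) — ``nu`` is
the coefficient of variation of individual growth variability, ``(m, s)``
the mean and SD of measurement error on the increment — and with
probability ``p`` it is an outlier, uniform over the observed increment
range.  Optional seasonality warps calendar time before ``dt`` is formed:
``t' = t + (u / 2 pi) * sin(2 pi (t - w))``.

Model variants (which of nu, s, m, p, u, w are freed) are compared by
likelihood-ratio gains (1.92 for one extra parameter, 3.0 for two) and by
AIC with a delta-AIC > 3 rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .tagging import IncrementDataset
from .vbgf import VBGFParams

__all__ = [
    "PARAM_NAMES",
    "FrancisParams",
    "FrancisFit",
    "seasonal_time",
    "expected_increment",
    "neg_log_likelihood",
    "fit",
    "to_vbgf",
    "compare_models",
    "residual_diagnostics",
]

#: Canonical parameter order for vectorised fitting.
PARAM_NAMES = ("g_alpha", "g_beta", "nu", "s", "m", "p", "u", "w")

#: Box bounds used by the optimiser.
_BOUNDS = {
    "g_alpha": (0.05, 30.0),
    "g_beta": (0.01, 30.0),
    "nu": (0.0, 5.0),
    "s": (0.0, 20.0),
    "m": (-10.0, 10.0),
    "p": (0.0, 1.0),
    "u": (0.0, 1.0),
    "w": (0.0, 1.0),
}

#: Floor (cm) for the growth-variability SD when the expected increment is
#: non-positive (shrinkage is not modelled; keeps the density proper for
#: animals released near or above L_inf).
SIGMA_FLOOR = 0.1


@dataclass(frozen=True)
class FrancisParams:
    """Growth-increment model parameters at reference lengths (alpha, beta)."""

    g_alpha: float
    g_beta: float
    nu: float = 0.0
    s: float = 0.0
    m: float = 0.0
    p: float = 0.0
    u: float = 0.0
    w: float = 0.0
    alpha: float = 100.0
    beta: float = 130.0

    def __post_init__(self) -> None:
        if self.alpha >= self.beta:
            raise ValueError("reference lengths must satisfy alpha < beta")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("outlier fraction p must be in [0, 1]")
        if not (0.0 <= self.u <= 1.0):
            raise ValueError("seasonal amplitude u must be in [0, 1]")
        if self.nu < 0 or self.s < 0:
            raise ValueError("nu and s must be non-negative")

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    def with_values(self, **kwargs) -> "FrancisParams":
        return replace(self, **kwargs)


def seasonal_time(t, u: float, w: float):
    """Warp decimal-year time(s) ``t`` by the seasonal growth cycle.

    ``t' = t + (u / 2 pi) * sin(2 pi (t - w))``; with ``u = 0`` this is the
    identity, and the warp over any whole year integrates to zero so annual
    increments are unaffected.
    """
    if not (0.0 <= u <= 1.0):
        raise ValueError("u must be in [0, 1]")
    t = np.asarray(t, dtype=float)
    out = t + (u / (2.0 * np.pi)) * np.sin(2.0 * np.pi * (t - w))
    return out if out.ndim else float(out)


def to_vbgf(params: FrancisParams, l0: float = 60.0) -> VBGFParams:
    """Convert reference-length increments to conventional VBGF (L_inf, k).

    ``l0`` (size at birth) is not estimable from increments and defaults to
    the 60 cm literature value used for curve generation.
    """
    ga, gb = params.g_alpha, params.g_beta
    if ga <= gb:
        raise ValueError("asymptote undefined: requires g_alpha > g_beta")
    a, b = params.alpha, params.beta
    l_inf = (b * ga - a * gb) / (ga - gb)
    k = -np.log(1.0 + (ga - gb) / (a - b))
    return VBGFParams(l_inf=float(l_inf), k=float(k), l0=l0)


def expected_increment(l1, dt, params: FrancisParams):
    """Mean increment (cm) for release length ``l1`` over ``dt`` years.

    ``dt`` is taken as already seasonally adjusted; the likelihood applies
    :func:`seasonal_time` to the calendar dates before calling this.
    """
    if params.g_alpha == params.g_beta:
        raise ValueError("degenerate growth curve: g_alpha == g_beta gives k = 0")
    vb = to_vbgf(params)
    l1 = np.asarray(l1, dtype=float)
    dt = np.asarray(dt, dtype=float)
    if np.any(dt <= 0):
        raise ValueError("dt must be positive")
    mu = (vb.l_inf - l1) * (1.0 - np.exp(-vb.k * dt))
    return mu if mu.ndim else float(mu)


def _mixture_density(
    increments: np.ndarray,
    mu: np.ndarray,
    params: FrancisParams,
    incr_range: float,
) -> np.ndarray:
    """Per-record contaminated-normal density values."""
    sigma_g = np.where(mu > 0, params.nu * mu, SIGMA_FLOOR if params.nu > 0 else 0.0)
    sd = np.sqrt(sigma_g**2 + params.s**2)
    f = np.zeros_like(increments)
    if params.p < 1.0:
        with np.errstate(divide="ignore", invalid="ignore"):
            core = stats.norm.pdf(increments, loc=mu + params.m, scale=sd)
        core = np.where(sd > 0, core, np.where(increments == mu + params.m, np.inf, 0.0))
        f += (1.0 - params.p) * core
    if params.p > 0.0:
        if incr_range <= 0:
            raise ValueError("outlier component needs a positive observed increment range")
        f += params.p / incr_range
    return f


def _adjusted_dt(ds: IncrementDataset, params: FrancisParams) -> np.ndarray:
    dt = ds.times_at_large
    if params.u == 0.0:
        return dt
    t1 = ds.release_times
    t2 = t1 + dt
    return seasonal_time(t2, params.u, params.w) - seasonal_time(t1, params.u, params.w)


def neg_log_likelihood(ds: IncrementDataset, params: FrancisParams) -> float:
    """Negative log-likelihood of the increment dataset under ``params``.

    Raises
    ------
    ValueError
        If any record's mixture density is zero or non-finite (for example a
        degenerate all-zero spread with ``p = 0``), naming the record.
    """
    if len(ds) == 0:
        raise ValueError("empty dataset")
    incr = ds.increments
    mu = expected_increment(ds.release_tl, _adjusted_dt(ds, params), params)
    mu = np.atleast_1d(mu)
    incr_range = float(np.ptp(incr)) if len(ds) > 1 else 0.0
    f = _mixture_density(incr, mu, params, incr_range)
    bad = ~np.isfinite(f) | (f <= 0)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise ValueError(
            f"non-finite likelihood for record {ds.records[i].individual_id!r} "
            f"(increment {incr[i]:.2f}, expected {mu[i]:.2f})"
        )
    return float(-np.sum(np.log(f)))


@dataclass(frozen=True)
class FrancisFit:
    """A fitted growth-increment model."""

    params: FrancisParams
    se: dict[str, float]
    loglik: float
    aic: float
    n: int
    free: tuple[str, ...]
    vbgf: VBGFParams
    residuals: np.ndarray
    expected: np.ndarray
    release_tl: np.ndarray
    converged: bool
    data_key: tuple = field(default=(), repr=False)

    @property
    def n_free(self) -> int:
        return len(self.free)

    def summary(self) -> str:
        rows = [f"Francis growth fit  (n={self.n}, free: {', '.join(self.free)})"]
        for name in PARAM_NAMES:
            val = getattr(self.params, name)
            se = self.se.get(name)
            tag = f"{val:8.3f}" + (f" ({se:.3f})" if se is not None and np.isfinite(se) else "  fixed")
            rows.append(f"  {name:8s} {tag}")
        rows.append(f"  loglik  {self.loglik:10.2f}   AIC {self.aic:8.2f}")
        rows.append(f"  L_inf   {self.vbgf.l_inf:8.2f} cm   k {self.vbgf.k:.4f} /yr")
        return "\n".join(rows)


def _dataset_key(ds: IncrementDataset) -> tuple:
    return (len(ds), ds.increments.tobytes(), ds.times_at_large.tobytes())


def _initial_values(ds: IncrementDataset, alpha: float, beta: float) -> dict[str, float]:
    """Moment-based starting values: regress annual growth rate on release length."""
    rate = ds.increments / ds.times_at_large
    l1 = ds.release_tl
    if len(ds) >= 3 and np.ptp(l1) > 0:
        slope, intercept = np.polyfit(l1, rate, 1)
    else:
        slope, intercept = 0.0, float(np.mean(rate))
    ga = max(intercept + slope * alpha, 0.2)
    gb = max(intercept + slope * beta, 0.05)
    if gb >= ga:
        gb = 0.5 * ga
    resid_sd = float(np.std(rate - (intercept + slope * l1))) if len(ds) > 2 else 1.0
    return {
        "g_alpha": ga,
        "g_beta": gb,
        "nu": 0.3,
        "s": float(np.clip(resid_sd, 0.5, 5.0)),
        "m": 0.0,
        "p": 0.02,
        "u": 0.3,
        "w": 0.5,
    }


def _numerical_hessian(fun, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    n = len(x)
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def fit(
    ds: IncrementDataset,
    free: Sequence[str] = ("g_alpha", "g_beta", "nu", "s"),
    fixed: dict[str, float] | None = None,
    alpha: float = 100.0,
    beta: float = 130.0,
    n_starts: int = 5,
    seed: int = 0,
    sex: str | None = None,
) -> FrancisFit:
    """Fit the growth-increment model by bounded multistart quasi-Newton.

    Parameters
    ----------
    free
        Names of parameters to estimate; must include ``g_alpha`` and
        ``g_beta``.  The rest are held at ``fixed`` (default 0).
    alpha, beta
        Reference lengths in cm (defaults 100 and 130).
    n_starts
        Number of jittered starts (+-20% around moment-based values).
    sex
        Optionally restrict to one sex before fitting.  Male-only fits are
        refused below n = 25 (too few recaptured males to be reliable).
    """
    free = tuple(free)
    if "g_alpha" not in free or "g_beta" not in free:
        raise ValueError("g_alpha and g_beta must be free")
    unknown = set(free) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
    if sex is not None:
        ds = ds.subset_sex(sex)
        if sex == "male" and len(ds) < 25:
            raise ValueError(
                f"male-only fit refused: only {len(ds)} male recaptures (< 25)"
            )
    if len(ds) < len(free) + 1:
        raise ValueError("fewer records than free parameters")

    base = {n: 0.0 for n in PARAM_NAMES}
    base.update(fixed or {})
    init = _initial_values(ds, alpha, beta)
    base["g_alpha"], base["g_beta"] = init["g_alpha"], init["g_beta"]

    def make_params(x: np.ndarray) -> FrancisParams:
        vals = dict(base)
        for name, v in zip(free, x):
            vals[name] = float(v)
        return FrancisParams(alpha=alpha, beta=beta, **vals)

    def objective(x: np.ndarray) -> float:
        vals = dict(base)
        for name, v in zip(free, x):
            vals[name] = float(v)
        if vals["g_alpha"] <= vals["g_beta"]:
            return 1e10
        if 1.0 + (vals["g_alpha"] - vals["g_beta"]) / (alpha - beta) <= 1e-9:
            return 1e10
        try:
            return neg_log_likelihood(ds, FrancisParams(alpha=alpha, beta=beta, **vals))
        except (ValueError, FloatingPointError):
            return 1e10

    rng = np.random.default_rng(seed)
    bounds = [_BOUNDS[n] for n in free]
    x0_base = np.array([init[n] for n in free])
    best = None
    diagnostics = []
    for start in range(n_starts):
        if start == 0:
            x0 = x0_base.copy()
        else:
            jitter = rng.uniform(0.8, 1.2, size=len(free))
            x0 = x0_base * jitter
            # additive jitter for parameters whose base value may be 0
            for idx, name in enumerate(free):
                if name in ("m", "w", "p", "u", "nu", "s"):
                    lo, hi = _BOUNDS[name]
                    x0[idx] = np.clip(x0[idx] + rng.uniform(-0.1, 0.1), lo, hi)
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        diagnostics.append(res.message)
        if res.fun < 1e9 and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(f"optimisation failed from all starts: {diagnostics}")

    params = make_params(best.x)
    nll = float(best.fun)
    loglik = -nll
    aic = 2.0 * len(free) - 2.0 * loglik

    # Wald SEs from the inverse numerical Hessian at the optimum.
    se = {n: None for n in PARAM_NAMES}
    try:
        H = _numerical_hessian(objective, best.x)
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        for name, v in zip(free, diag):
            se[name] = float(np.sqrt(v)) if v > 0 else np.nan
    except np.linalg.LinAlgError:
        warnings.warn("singular Hessian: standard errors unavailable", stacklevel=2)
        for name in free:
            se[name] = np.nan

    mu = np.atleast_1d(expected_increment(ds.release_tl, _adjusted_dt(ds, params), params))
    residuals = ds.increments - mu
    return FrancisFit(
        params=params,
        se={k: v for k, v in se.items() if v is not None},
        loglik=loglik,
        aic=aic,
        n=len(ds),
        free=free,
        vbgf=to_vbgf(params),
        residuals=residuals,
        expected=mu,
        release_tl=ds.release_tl,
        converged=bool(best.success),
        data_key=_dataset_key(ds),
    )


def compare_models(fits: Sequence[FrancisFit]) -> dict:
    """Likelihood-ratio and AIC comparison of nested model variants.

    Fits must be on identical data.  For every nested pair (free set of one
    model strictly contained in another's) the log-likelihood gain is
    compared with 1.92 for one extra parameter and 3.0 for two or more.
    The flagged best model is chosen by stepwise LRT from the simplest
    model, breaking ties by AIC.
    """
    fits = list(fits)
    if len(fits) < 1:
        raise ValueError("need at least one fit")
    key = fits[0].data_key
    if any(f.data_key != key for f in fits):
        raise ValueError("fits were not produced from identical datasets")

    pairs = []
    for i, fa in enumerate(fits):
        for j, fb in enumerate(fits):
            if i == j or not (set(fa.free) < set(fb.free)):
                continue
            extra = fb.n_free - fa.n_free
            gain = fb.loglik - fa.loglik
            threshold = 1.92 if extra == 1 else 3.0
            pairs.append(
                {
                    "simpler": i,
                    "richer": j,
                    "extra_params": extra,
                    "loglik_gain": gain,
                    "threshold": threshold,
                    "richer_preferred": gain > threshold,
                }
            )

    order = sorted(range(len(fits)), key=lambda i: (fits[i].n_free, fits[i].aic))
    best = order[0]
    for j in order[1:]:
        if set(fits[best].free) < set(fits[j].free):
            extra = fits[j].n_free - fits[best].n_free
            gain = fits[j].loglik - fits[best].loglik
            if gain > (1.92 if extra == 1 else 3.0):
                best = j

    table = [
        {
            "model": i,
            "free": ",".join(f.free),
            "n_free": f.n_free,
            "loglik": f.loglik,
            "aic": f.aic,
            "delta_aic": f.aic - min(g.aic for g in fits),
        }
        for i, f in enumerate(fits)
    ]
    return {"table": table, "lrt_pairs": pairs, "best_index": best}


def residual_diagnostics(fit: FrancisFit) -> dict:
    """Heteroskedasticity diagnostics for a fitted model.

    Under the growth-variability assumption the absolute residual should
    shrink with release length and grow with predicted growth; both trends
    are summarised by Spearman rank correlations.
    """
    if fit.residuals is None or len(fit.residuals) == 0:
        raise ValueError("fit carries no residuals")
    ab = np.abs(fit.residuals)
    rho_release = stats.spearmanr(fit.release_tl, ab).statistic
    rho_pred = stats.spearmanr(fit.expected, ab).statistic
    return {
        "release_tl": fit.release_tl,
        "predicted_growth": fit.expected,
        "residual": fit.residuals,
        "rho_absresid_release": float(rho_release),
        "rho_absresid_predicted": float(rho_pred),
    }
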