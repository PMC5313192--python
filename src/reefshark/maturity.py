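"""Maturity ogives, length-length conversions and descriptive tests.

Male maturity is assessed from clasper calcification.  The ogive is a
binomial-logit regression of maturity (calcified = 1, not calcified = 0;
partially calcified animals are excluded) on total length; the length at
50% maturity is ``L50 = -b0/b1``.  Confidence intervals come from a
percentile bootstrap over individuals.

Length-length conversions (TL/FL/PCL) are ordinary least-squares fits for
each directed pair, optionally compared pooled versus with sex terms by
AIC (a sex model is only preferred when it lowers AIC by more than 3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .tagging import MaturityObservation

__all__ = [
    "MaturityFit",
    "ConversionModel",
    "LMAX_RELATION",
    "fit_ogive",
    "bootstrap_logistic",
    "maturity_from_lmax",
    "fit_conversions",
    "study_conversions",
    "welch_t",
    "sex_ratio_chisq",
]

#: Elasmobranch-wide linear relation length-at-maturity = a + b * max-length
#: (cm TL).  Confirmed by reproducing the study's 116.7 cm at TL_max = 175.5.
LMAX_RELATION = (11.09, 0.602)


@dataclass(frozen=True)
class MaturityFit:
    """Logistic maturity ogive with bootstrap uncertainty."""

    b0: float
    b1: float
    l50: float
    ci95: tuple[float, float]
    n_used: int
    bootstrap_reps: int
    b0_ci95: tuple[float, float]
    b1_ci95: tuple[float, float]

    def proportion_mature(self, tl):
        eta = self.b0 + self.b1 * np.asarray(tl, dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass(frozen=True)
class ConversionModel:
    """Directed linear length conversion ``y = b0 + b1 * x`` (cm)."""

    from_measure: str
    to_measure: str
    b0: float
    b1: float
    se_b0: float
    se_b1: float
    r2: float
    df: int

    def __post_init__(self) -> None:
        if self.b1 <= 0:
            raise ValueError("conversion slope must be positive")
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError("r2 must lie in [0, 1]")

    def predict(self, x):
        out = self.b0 + self.b1 * np.asarray(x, dtype=float)
        return out if out.ndim else float(out)


def _logistic_newton(x: np.ndarray, y: np.ndarray, idx: np.ndarray,
                     max_iter: int = 30, tol: float = 1e-8) -> np.ndarray:
    """Vectorised 2-parameter logistic fits over resample index rows.

    ``idx`` has shape (B, n); returns (B, 2) array of (b0, b1).  A plain
    Newton-Raphson on the binomial log-likelihood, run simultaneously for
    all B bootstrap samples; linear predictors are clipped at +-30 so
    (near-)separated resamples saturate instead of overflowing.
    """
    xb = x[idx]
    yb = y[idx]
    B = idx.shape[0]
    b0 = np.full(B, float(np.log(max(y.mean(), 1e-3) / max(1 - y.mean(), 1e-3))))
    b1 = np.zeros(B)
    for _ in range(max_iter):
        eta = np.clip(b0[:, None] + b1[:, None] * xb, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        r = yb - mu
        g0 = r.sum(axis=1)
        g1 = (r * xb).sum(axis=1)
        h00 = w.sum(axis=1)
        h01 = (w * xb).sum(axis=1)
        h11 = (w * xb * xb).sum(axis=1)
        det = h00 * h11 - h01 * h01
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        # damp steps to keep saturated samples stable
        step = np.maximum(1.0, np.abs(d1) / 2.0)
        b0 += d0 / step
        b1 += d1 / step
        if np.max(np.abs(d0)) < tol and np.max(np.abs(d1)) < tol:
            break
    return np.column_stack([b0, b1])


def bootstrap_logistic(
    x: np.ndarray, y: np.ndarray, reps: int, seed: int, chunk: int = 2000
) -> np.ndarray:
    """Percentile-bootstrap draws of logistic coefficients (resampling individuals)."""
    rng = np.random.default_rng(seed)
    n = len(x)
    out = np.empty((reps, 2))
    done = 0
    while done < reps:
        b = min(chunk, reps - done)
        idx = rng.integers(0, n, size=(b, n))
        out[done : done + b] = _logistic_newton(x, y, idx)
        done += b
    return out


def fit_ogive(
    obs: Sequence[MaturityObservation],
    bootstrap_reps: int = 10_000,
    seed: int = 0,
) -> MaturityFit:
    """Fit the male maturity ogive with a bootstrap CI on L50.

    Partially calcified animals are excluded; at least 10 observations of
    each remaining class are required.  The point fit is a statsmodels
    binomial GLM (IRLS); bootstrap resamples individuals and reports
    percentile 95% intervals.
    """
    pairs = [
        (o.tl, 1.0 if o.clasper_state == "calcified" else 0.0)
        for o in obs
        if o.clasper_state in ("calcified", "not_calcified")
    ]
    if not pairs:
        raise ValueError("no usable (calcified / not calcified) observations")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    n_mat, n_imm = int(y.sum()), int((1 - y).sum())
    if min(n_mat, n_imm) < 10:
        raise ValueError(
            f"need >= 10 observations per class, got mature={n_mat}, immature={n_imm}"
        )
    if x[y == 0].max() < x[y == 1].min():
        raise ValueError(
            "complete separation: every immature animal is shorter than every "
            f"mature one (threshold near {0.5 * (x[y == 0].max() + x[y == 1].min()):.1f} cm)"
        )

    X = sm.add_constant(x)
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    b0, b1 = float(res.params[0]), float(res.params[1])
    if b1 <= 0:
        raise ValueError("fitted slope is non-positive: maturity does not increase with length")
    l50 = -b0 / b1

    draws = bootstrap_logistic(x, y, bootstrap_reps, seed)
    valid = draws[:, 1] > 0
    if valid.mean() < 0.99:
        warnings.warn(
            f"{(~valid).sum()} bootstrap resamples had non-positive slopes", stacklevel=2
        )
    l50_draws = -draws[valid, 0] / draws[valid, 1]
    lo, hi = np.percentile(l50_draws, [2.5, 97.5])
    b0_ci = tuple(np.percentile(draws[valid, 0], [2.5, 97.5]))
    b1_ci = tuple(np.percentile(draws[valid, 1], [2.5, 97.5]))
    return MaturityFit(
        b0=b0,
        b1=b1,
        l50=float(l50),
        ci95=(float(lo), float(hi)),
        n_used=len(x),
        bootstrap_reps=bootstrap_reps,
        b0_ci95=(float(b0_ci[0]), float(b0_ci[1])),
        b1_ci95=(float(b1_ci[0]), float(b1_ci[1])),
    )


def maturity_from_lmax(tl_max: float, relation: tuple[float, float] = LMAX_RELATION) -> float:
    """Length at maturity predicted from maximum observed length (cm TL)."""
    if tl_max <= 0:
        raise ValueError("tl_max must be positive")
    if relation is None or len(relation) != 2:
        raise ValueError("relation must be a pair (intercept, slope)")
    a, b = relation
    return float(a + b * tl_max)


_MEASURES = ("tl", "fl", "pcl")


def fit_conversions(
    lengths: pd.DataFrame, compare_sex: bool = False, min_pairs: int = 30
) -> dict:
    """OLS length-length conversions for all directed measure pairs.

    ``lengths`` needs columns ``tl``, ``fl``, ``pcl`` (blanks allowed) and
    ``sex`` when ``compare_sex``.  Each pair requires ``min_pairs`` complete
    rows.  With ``compare_sex``, a pooled model is compared by AIC with one
    adding sex to slope and intercept; the sex model is preferred only when
    it lowers AIC by more than 3.
    """
    models: dict[tuple[str, str], ConversionModel] = {}
    aic_rows = []
    for xm in _MEASURES:
        for ym in _MEASURES:
            if xm == ym or xm not in lengths.columns or ym not in lengths.columns:
                continue
            sub = lengths[[xm, ym] + (["sex"] if compare_sex else [])].dropna()
            if len(sub) < min_pairs:
                warnings.warn(
                    f"{xm}->{ym}: only {len(sub)} complete pairs (< {min_pairs}), skipped",
                    stacklevel=2,
                )
                continue
            x = sub[xm].to_numpy(dtype=float)
            y = sub[ym].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                raise ValueError(f"{xm}->{ym}: predictor is constant (rank deficient)")
            res = sm.OLS(y, sm.add_constant(x)).fit()
            models[(xm.upper(), ym.upper())] = ConversionModel(
                from_measure=xm.upper(),
                to_measure=ym.upper(),
                b0=float(res.params[0]),
                b1=float(res.params[1]),
                se_b0=float(res.bse[0]),
                se_b1=float(res.bse[1]),
                r2=float(res.rsquared),
                df=int(res.df_resid),
            )
            if compare_sex:
                is_f = (sub["sex"] == "female").to_numpy(dtype=float)
                Xs = np.column_stack([np.ones_like(x), x, is_f, is_f * x])
                res_sex = sm.OLS(y, Xs).fit()
                aic_rows.append(
                    {
                        "pair": f"{xm.upper()}->{ym.upper()}",
                        "aic_pooled": float(res.aic),
                        "aic_sex": float(res_sex.aic),
                        "delta_aic": float(res.aic - res_sex.aic),
                        "sex_preferred": (res.aic - res_sex.aic) > 3.0,
                    }
                )
    if not models:
        raise ValueError("no conversion could be fitted")
    return {"models": models, "aic_table": pd.DataFrame(aic_rows) if compare_sex else None}


def study_conversions() -> dict[tuple[str, str], ConversionModel]:
    """The packaged study conversion coefficients (sexes pooled)."""
    path = resources.files("reefshark.data") / "length_conversions.csv"
    df = pd.read_csv(path)
    return {
        (r["x"], r["y"]): ConversionModel(
            from_measure=r["x"],
            to_measure=r["y"],
            b0=float(r["b0"]),
            b1=float(r["b1"]),
            se_b0=float(r["se_b0"]),
            se_b1=float(r["se_b1"]),
            r2=float(r["r2"]),
            df=int(r["df"]),
        )
        for _, r in df.iterrows()
    }


def welch_t(mean1, sd1, n1, mean2, sd2, n2) -> tuple[float, float]:
    """Unequal-variance t statistic and Welch-Satterthwaite df from summaries."""
    if min(n1, n2) < 2:
        raise ValueError("need n >= 2 per group")
    if min(sd1, sd2) <= 0:
        raise ValueError("standard deviations must be positive")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(t), float(df)


def sex_ratio_chisq(n_male: int, n_female: int) -> tuple[float, float]:
    """Goodness-of-fit chi-square (1 df, no continuity correction) against 1:1."""
    if n_male < 0 or n_female < 0 or n_male + n_female == 0:
        raise ValueError("counts must be non-negative with a positive total")
    n = n_male + n_female
    chi2 = (n_male - n_female) ** 2 / n
    from scipy import stats as sps

    return float(chi2), float(sps.chi2.sf(chi2, df=1))
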