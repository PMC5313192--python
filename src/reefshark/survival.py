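"""Bayesian Jolly-Seber survival from annual capture histories.

Open-population mark-recapture: individuals enter the study area
(recruitment/immigration), survive year to year with constant probability
``phi``, and are detected in year ``t`` with probability ``p_t`` while
alive.  The restricted dynamic-occupancy formulation tracks a latent
state per individual and occasion — not yet entered, alive, or dead —
with no re-entry after death.  The unknown superpopulation size is
handled by data augmentation: a pool of all-zero pseudo-histories is
appended and each pseudo-individual may or may not ever enter.

Priors are U(0,1) on ``phi``, every ``p_t`` and every entry probability
``gamma_t``.  Sampling alternates exact forward-filtering
backward-sampling of the three-state latent trajectories with conjugate
Beta draws for the probabilities, so chains mix quickly; convergence is
monitored with the classical Gelman-Rubin statistic (r-hat < 1.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CaptureHistoryMatrix",
    "JSModelConfig",
    "JSPosterior",
    "build_histories",
    "fit_js",
    "survival_to_mortality",
    "gelman_rubin",
]

_NOT_ENTERED, _ALIVE, _DEAD = 0, 1, 2


@dataclass(frozen=True)
class CaptureHistoryMatrix:
    """0/1 detections, one row per observed individual, one column per year."""

    y: np.ndarray
    occasion_dates: tuple[int, ...]
    individual_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        y = np.asarray(self.y)
        if y.ndim != 2 or not np.isin(y, (0, 1)).all():
            raise ValueError("y must be a 2-D 0/1 matrix")
        if y.shape[1] != len(self.occasion_dates):
            raise ValueError("one occasion date per column required")
        if any(b <= a for a, b in zip(self.occasion_dates, self.occasion_dates[1:])):
            raise ValueError("occasions must be strictly increasing")
        if y.shape[0] and (y.sum(axis=1) == 0).any():
            raise ValueError("every observed row must have at least one detection")
        object.__setattr__(self, "y", y.astype(np.int8))

    @property
    def n_observed(self) -> int:
        return int(self.y.shape[0])

    @property
    def n_occasions(self) -> int:
        return int(self.y.shape[1])

    def to_frame(self) -> pd.DataFrame:
        ids = self.individual_ids or tuple(str(i) for i in range(self.n_observed))
        return pd.DataFrame(self.y, index=list(ids), columns=list(self.occasion_dates))


@dataclass(frozen=True)
class JSModelConfig:
    """Run configuration for the data-augmentation sampler."""

    seed: int
    augment_factor: float = 3.0
    chains: int = 3
    iterations: int = 25_000
    burn_in: int = 5_000
    constant_p: bool = False
    fix_p: float | None = None  # pin detection (e.g. 0.0 for data-free runs)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.fix_p is not None and not (0.0 <= self.fix_p <= 1.0):
            raise ValueError("fix_p must be a probability")
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.augment_factor < 1:
            raise ValueError("augment_factor must be >= 1")
        if self.chains < 1:
            raise ValueError("need at least one chain")


@dataclass(frozen=True)
class JSPosterior:
    """Posterior draws and summaries for phi, p_t, gamma_t and superpopulation size."""

    draws: dict[str, np.ndarray]  # name -> (chains, n_kept)
    summary: pd.DataFrame  # mean, ci2.5, ci97.5, rhat per parameter
    converged: bool
    config: JSModelConfig
    z_sample: np.ndarray = field(repr=False, default=None)  # one latent state draw

    def mean(self, name: str) -> float:
        return float(self.draws[name].mean())

    def ci95(self, name: str) -> tuple[float, float]:
        lo, hi = np.percentile(self.draws[name], [2.5, 97.5])
        return float(lo), float(hi)


def build_histories(events: pd.DataFrame, years: Sequence[int]) -> CaptureHistoryMatrix:
    """Bin capture events into an annual 0/1 matrix.

    ``events`` needs ``individual_id`` and ``date`` columns (dates or
    years); repeat captures within a year collapse to a single 1.  An
    event outside the occasion span is an error.
    """
    years = list(years)
    if "individual_id" not in events.columns or "date" not in events.columns:
        raise ValueError("events must have individual_id and date columns")
    ev_years = events["date"].map(
        lambda d: int(d) if isinstance(d, (int, np.integer)) else pd.Timestamp(d).year
    )
    outside = ~ev_years.isin(years)
    if outside.any():
        bad = sorted(ev_years[outside].unique())
        raise ValueError(f"events outside occasion span {years[0]}-{years[-1]}: years {bad}")
    ids = sorted(events["individual_id"].astype(str).unique())
    id_index = {v: i for i, v in enumerate(ids)}
    col = {y: j for j, y in enumerate(years)}
    y = np.zeros((len(ids), len(years)), dtype=np.int8)
    for iid, yr in zip(events["individual_id"].astype(str), ev_years):
        y[id_index[iid], col[yr]] = 1
    return CaptureHistoryMatrix(y=y, occasion_dates=tuple(years), individual_ids=tuple(ids))


def _init_states(y: np.ndarray) -> np.ndarray:
    """Initial latent states: alive between first and last detection."""
    M, T = y.shape
    S = np.zeros((M, T), dtype=np.int8)
    detected = y.sum(axis=1) > 0
    if detected.any():
        first = np.argmax(y, axis=1)
        last = T - 1 - np.argmax(y[:, ::-1], axis=1)
        tt = np.arange(T)
        alive = detected[:, None] & (tt >= first[:, None]) & (tt <= last[:, None])
        S[alive] = _ALIVE
    return S


def _sample_states(
    y1: np.ndarray, phi: float, p: np.ndarray, gamma: np.ndarray, rng
) -> np.ndarray:
    """Exact draw of latent trajectories by forward filtering, backward sampling.

    ``y1`` is the (M, T) boolean detection matrix.  States per occasion are
    0 = not yet entered, 1 = alive, 2 = dead; detection is only possible
    while alive, entry happens at most once, death is absorbing.
    """
    M, T = y1.shape
    alpha = np.empty((T, M, 3))
    # emission: y=1 has prob p_t while alive and 0 otherwise; y=0 has
    # prob 1-p_t alive and 1 otherwise
    e_alive = np.where(y1[:, 0], p[0], 1.0 - p[0])
    e_other = np.where(y1[:, 0], 0.0, 1.0)
    a = alpha[0]
    a[:, 0] = (1.0 - gamma[0]) * e_other
    a[:, 1] = gamma[0] * e_alive
    a[:, 2] = 0.0
    a /= a.sum(axis=1, keepdims=True)
    for t in range(1, T):
        prev = alpha[t - 1]
        e_alive = np.where(y1[:, t], p[t], 1.0 - p[t])
        e_other = np.where(y1[:, t], 0.0, 1.0)
        a = alpha[t]
        a[:, 0] = prev[:, 0] * (1.0 - gamma[t]) * e_other
        a[:, 1] = (prev[:, 0] * gamma[t] + prev[:, 1] * phi) * e_alive
        a[:, 2] = (prev[:, 1] * (1.0 - phi) + prev[:, 2]) * e_other
        a /= a.sum(axis=1, keepdims=True)

    S = np.empty((M, T), dtype=np.int8)
    u = rng.random((T, M))
    a = alpha[T - 1]
    c1 = a[:, 0]
    c2 = c1 + a[:, 1]
    tot = c2 + a[:, 2]
    S[:, T - 1] = (u[T - 1] * tot > c1).astype(np.int8) + (u[T - 1] * tot > c2)
    for t in range(T - 2, -1, -1):
        nxt = S[:, t + 1]
        a = alpha[t]
        # transition probabilities into the sampled next state
        g, ph = gamma[t + 1], phi
        w0 = a[:, 0] * np.choose(nxt, [1.0 - g, g, 0.0])
        w1 = a[:, 1] * np.choose(nxt, [0.0, ph, 1.0 - ph])
        w2 = a[:, 2] * np.choose(nxt, [0.0, 0.0, 1.0])
        tot = w0 + w1 + w2
        r = u[t] * tot
        S[:, t] = (r > w0).astype(np.int8) + (r > w0 + w1)
    return S


def _collapsed_loglik(
    pats: np.ndarray, counts: np.ndarray, phi: float, p: np.ndarray, gamma: np.ndarray
) -> float:
    """Marginal log-likelihood with latent states integrated out.

    Forward algorithm over the (H, T) unique capture-history patterns,
    weighted by their multiplicities — the exact likelihood the Metropolis
    updates target, free of latent-state coupling.
    """
    H, T = pats.shape
    e_alive = np.where(pats[:, 0], p[0], 1.0 - p[0])
    e_other = 1.0 - pats[:, 0]
    f0 = (1.0 - gamma[0]) * e_other
    f1 = gamma[0] * e_alive
    f2 = np.zeros(H)
    for t in range(1, T):
        e_alive = np.where(pats[:, t], p[t], 1.0 - p[t])
        e_other = 1.0 - pats[:, t]
        f0, f1, f2 = (
            f0 * (1.0 - gamma[t]) * e_other,
            (f0 * gamma[t] + f1 * phi) * e_alive,
            (f1 * (1.0 - phi) + f2) * e_other,
        )
    lik = f0 + f1 + f2
    if np.any(lik <= 0):
        return -np.inf
    return float(counts @ np.log(lik))


def _run_chain(
    y: np.ndarray,
    n_observed: int,
    cfg: JSModelConfig,
    seed: int,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """One MCMC chain; returns kept draws and a final latent-state draw.

    The kernel is Metropolis-within-Gibbs on the collapsed (marginal)
    likelihood: each probability parameter takes a logit-scale random-walk
    step accepted against the forward-algorithm likelihood over unique
    history patterns, so mixing does not suffer from latent-state
    coupling.  Step sizes adapt toward ~44% acceptance during burn-in
    only.  The superpopulation size is drawn exactly: each of the
    augmented all-zero histories entered the population with the
    closed-form conditional probability
    ``1 - prod_t(1 - gamma_t) / P(all-zero history)``.
    """
    rng = np.random.default_rng(seed)
    M, T = y.shape
    n_aug = M - n_observed
    pats, counts = np.unique(y, axis=0, return_counts=True)
    pats = pats.astype(bool)
    counts = counts.astype(float)
    zero_pat = ~pats.any(axis=1)

    # parameter vector: [phi, p_1..p_T, gamma_1..gamma_T]
    theta = np.empty(1 + 2 * T)
    theta[0] = rng.uniform(0.2, 0.9)
    theta[1 : 1 + T] = cfg.fix_p if cfg.fix_p is not None else rng.uniform(0.05, 0.5, T)
    theta[1 + T :] = rng.uniform(0.05, 0.5, T)
    if cfg.fix_p is not None:
        update_ids: list[int] = [0] + list(range(1 + T, 1 + 2 * T))
    elif cfg.constant_p:
        update_ids = [0, 1] + list(range(1 + T, 1 + 2 * T))
    else:
        update_ids = list(range(1 + 2 * T))
    steps = np.full(1 + 2 * T, 0.8)

    def split(th):
        p = np.full(T, th[1]) if cfg.constant_p else th[1 : 1 + T]
        return th[0], p, th[1 + T :]

    cur = _collapsed_loglik(pats, counts, *split(theta))
    n_kept = cfg.iterations - cfg.burn_in
    out = {
        "phi": np.empty(n_kept),
        "N_super": np.empty(n_kept),
        "p": np.empty((n_kept, T)),
        "gamma": np.empty((n_kept, T)),
    }
    accept = np.zeros(1 + 2 * T)

    for it in range(cfg.iterations):
        for j in update_ids:
            x = theta[j]
            z = np.log(x / (1.0 - x)) + steps[j] * rng.normal()
            x_new = 1.0 / (1.0 + np.exp(-z))
            theta[j] = x_new
            new = _collapsed_loglik(pats, counts, *split(theta))
            # symmetric walk on the logit scale: Jacobian x(1-x) enters
            log_ratio = new - cur + np.log(x_new * (1 - x_new)) - np.log(x * (1 - x))
            if np.log(rng.random()) < log_ratio:
                cur = new
                accept[j] += 1
            else:
                theta[j] = x
            if it < cfg.burn_in and (it + 1) % 100 == 0:
                rate = accept[j] / 100.0
                steps[j] *= np.exp(0.5 * (rate - 0.44))
                accept[j] = 0.0

        if it >= cfg.burn_in:
            k = it - cfg.burn_in
            phi, p, gamma = split(theta)
            out["phi"][k] = phi
            out["p"][k] = p
            out["gamma"][k] = gamma
            # exact superpopulation draw from the augmentation
            if n_aug > 0:
                never_enter = float(np.prod(1.0 - gamma))
                lik_zero = np.exp(
                    _collapsed_loglik(pats[zero_pat], np.ones(zero_pat.sum()), phi, p, gamma)
                ) if zero_pat.any() else 1.0
                p_entered = 1.0 - min(never_enter / lik_zero, 1.0)
                out["N_super"][k] = n_observed + rng.binomial(n_aug, p_entered)
            else:
                out["N_super"][k] = n_observed

    phi, p, gamma = split(theta)
    S = _sample_states(y == 1, phi, p, gamma, rng)
    return out, S


def fit_js(
    chm: CaptureHistoryMatrix,
    cfg: JSModelConfig,
    allow_no_observations: bool = False,
) -> JSPosterior:
    """Fit the augmented Jolly-Seber model by Gibbs sampling.

    Requires at least 20 observed individuals over at least 3 occasions
    (relaxable via ``allow_no_observations`` for prior-predictive runs).
    Results are returned regardless of convergence; any monitored r-hat
    at or above 1.1 flags the posterior as non-converged.
    """
    if chm.n_occasions < 3:
        raise ValueError("need at least 3 occasions")
    if chm.n_observed == 0 and not allow_no_observations:
        raise ValueError("no observed individuals (all-augmented input)")
    if chm.n_observed < 20 and not allow_no_observations:
        raise ValueError(f"need >= 20 observed individuals, got {chm.n_observed}")

    n = max(chm.n_observed, 1)
    n_aug = int(np.ceil(cfg.augment_factor * n))
    y = np.vstack([chm.y, np.zeros((n_aug, chm.n_occasions), dtype=np.int8)])

    per_chain = []
    z_sample = None
    for c in range(cfg.chains):
        draws, S = _run_chain(y, chm.n_observed, cfg, seed=cfg.seed + c)
        per_chain.append(draws)
        if c == 0:
            z_sample = S
    T = chm.n_occasions
    draws: dict[str, np.ndarray] = {
        "phi": np.stack([d["phi"] for d in per_chain]),
        "N_super": np.stack([d["N_super"] for d in per_chain]),
    }
    for t in range(T):
        draws[f"p[{t + 1}]"] = np.stack([d["p"][:, t] for d in per_chain])
        draws[f"gamma[{t + 1}]"] = np.stack([d["gamma"][:, t] for d in per_chain])

    rows = []
    for name, arr in draws.items():
        lo, hi = np.percentile(arr, [2.5, 97.5])
        rhat = gelman_rubin(arr) if cfg.chains >= 2 else np.nan
        rows.append(
            {"parameter": name, "mean": arr.mean(), "ci2.5": lo, "ci97.5": hi, "rhat": rhat}
        )
    summary = pd.DataFrame(rows).set_index("parameter")
    converged = bool((summary["rhat"].dropna() < 1.1).all())
    return JSPosterior(
        draws=draws, summary=summary, converged=converged, config=cfg, z_sample=z_sample
    )


def survival_to_mortality(phi: float) -> tuple[float, float]:
    """Annual mortality ``1 - phi`` and instantaneous rate ``Z = -ln(phi)``."""
    if not (0.0 < phi <= 1.0):
        raise ValueError("phi must be in (0, 1]")
    return float(1.0 - phi), float(-np.log(phi))


def gelman_rubin(chains: np.ndarray) -> float:
    """Classical potential scale reduction factor for one scalar parameter.

    ``chains`` has shape (m, n): m >= 2 chains of n draws each.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = chains.shape
    chain_means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = n * chain_means.var(ddof=1)
    if W == 0:
        return 1.0 if B == 0 else np.inf
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))
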