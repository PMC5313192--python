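"""Conventional von Bertalanffy curves, growth-at-length and longevity.

``L(t) = L_inf - (L_inf - L0) * exp(-k t)``: length approaches the
asymptote ``L_inf`` at rate ``k`` from size at birth ``L0``.  Growth at
length — the expected annual increment of an animal currently ``l`` cm
long, ``(L_inf - l)(1 - e^{-k})`` — is the comparable quantity across
studies that used different data types (age-length versus tagging).

Longevity is taken as the time to reach >99% of ``L_inf``,
``T_max = 5 ln(2) / k``.  Note an internal inconsistency in the source
study being reproduced: with k = 0.054 this formula gives ~64.2 yr, yet
the study reports 18.06 yr and feeds that value to its mortality
estimators.  Both numbers are surfaced here — :func:`longevity` returns
the formula value, and :data:`PRINTED_TMAX` carries the reported one for
reproduction runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "VBGFParams",
    "StudyGrowthEntry",
    "PRINTED_TMAX",
    "length_at_age",
    "growth_at_length",
    "longevity",
    "load_study_table",
    "comparison_table",
]

#: Longevity (years) as reported by the Palmyra study and used by its
#: Hoenig mortality calculations; NOT equal to 5 ln2 / 0.054 (see module docs).
PRINTED_TMAX = 18.06


@dataclass(frozen=True)
class VBGFParams:
    """Conventional VBGF parameters: asymptote, growth coefficient, size at birth."""

    l_inf: float
    k: float
    l0: float = 60.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if not (self.l_inf > self.l0 >= 0):
            raise ValueError("requires l_inf > l0 >= 0")


@dataclass(frozen=True)
class StudyGrowthEntry:
    """One published growth study for the cross-region comparison."""

    location: str
    latitude: str
    vbgf: VBGFParams | None
    g130_printed: float | None
    n: int
    method: str
    fl_inf: float | None = None
    pcl_inf: float | None = None


def length_at_age(p: VBGFParams, t):
    """Mean length (cm) at age ``t`` years."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("age must be non-negative")
    out = p.l_inf - (p.l_inf - p.l0) * np.exp(-p.k * t)
    return out if out.ndim else float(out)


def growth_at_length(p: VBGFParams, l: float) -> float:
    """Expected annual increment (cm/yr) at current length ``l``."""
    if l >= p.l_inf:
        warnings.warn(
            f"length {l} at or above asymptote {p.l_inf}: growth set to 0", stacklevel=2
        )
        return 0.0
    return float((p.l_inf - l) * (1.0 - np.exp(-p.k)))


def longevity(k: float) -> float:
    """Years to attain >99% of the asymptote: ``5 ln(2) / k``."""
    if k <= 0:
        raise ValueError("k must be positive")
    return 5.0 * np.log(2.0) / k


def load_study_table() -> list[StudyGrowthEntry]:
    """Published growth parameters by region (packaged comparison data).

    Literature values are carried as printed, not recomputed — the sources'
    unrounded parameters are unavailable.
    """
    path = resources.files("reefshark.data") / "growth_studies.csv"
    df = pd.read_csv(path)
    entries = []
    for _, r in df.iterrows():
        vb = None
        if np.isfinite(r["tl_inf"]) and np.isfinite(r["k"]) and np.isfinite(r["l0"]):
            vb = VBGFParams(l_inf=float(r["tl_inf"]), k=float(r["k"]), l0=float(r["l0"]))
        entries.append(
            StudyGrowthEntry(
                location=r["location"],
                latitude=r["latitude"],
                vbgf=vb,
                g130_printed=float(r["g130"]) if np.isfinite(r["g130"]) else None,
                n=int(r["n"]),
                method=r["method"],
                fl_inf=float(r["fl_inf"]) if np.isfinite(r["fl_inf"]) else None,
                pcl_inf=float(r["pcl_inf"]) if np.isfinite(r["pcl_inf"]) else None,
            )
        )
    return entries


def comparison_table(
    entries: list[StudyGrowthEntry],
    conversions: dict | None = None,
    max_age: float = 30.0,
    step: float = 0.1,
) -> dict:
    """Cross-study comparison: growth at 130 cm and sampled growth curves.

    Parameters
    ----------
    conversions
        Optional mapping ``{("TL","FL"): ConversionModel, ...}`` (see
        :func:`reefshark.maturity.study_conversions`) used to derive FL/PCL
        asymptotes for entries that report only a TL asymptote.

    Returns a dict with a ``table`` DataFrame and ``curves``
    (location -> (ages, lengths)); entries without a size at birth are
    skipped from the curves with a warning.
    """
    rows, curves = [], {}
    ages = np.arange(0.0, max_age + step / 2, step)
    for e in entries:
        row = {
            "location": e.location,
            "latitude": e.latitude,
            "tl_inf": e.vbgf.l_inf if e.vbgf else np.nan,
            "k": e.vbgf.k if e.vbgf else np.nan,
            "n": e.n,
            "method": e.method,
            "g130_printed": e.g130_printed,
            "g130_computed": np.nan,
            "fl_inf": e.fl_inf,
            "pcl_inf": e.pcl_inf,
        }
        if e.vbgf is None:
            warnings.warn(f"{e.location}: missing VBGF parameters, curve skipped", stacklevel=2)
        else:
            row["g130_computed"] = (
                growth_at_length(e.vbgf, 130.0) if e.vbgf.l_inf > 130.0 else 0.0
            )
            curves[e.location] = (ages, length_at_age(e.vbgf, ages))
            if conversions is not None:
                if row["fl_inf"] is None and ("TL", "FL") in conversions:
                    row["fl_inf"] = conversions[("TL", "FL")].predict(e.vbgf.l_inf)
                if row["pcl_inf"] is None and ("TL", "PCL") in conversions:
                    row["pcl_inf"] = conversions[("TL", "PCL")].predict(e.vbgf.l_inf)
        rows.append(row)
    return {"table": pd.DataFrame(rows), "curves": curves}
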