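"""Indirect total mortality from longevity (Hoenig log-log regressions).

Across well-studied taxa, total instantaneous mortality ``Z`` scales with
maximum age as ``ln Z = a + b ln(T_max)`` with ``b < 0``.  Two classical
coefficient sets are carried: teleost fishes, and cetaceans — the latter
often applied to sharks, whose demography resembles cetaceans more than
bony fishes.  In an unfished population ``Z`` equals natural mortality
``M``, so these estimates are directly comparable with ``1 - phi`` and
``-ln(phi)`` from a tag-recapture survival estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .survival import survival_to_mortality

__all__ = ["HoenigCoefficients", "TELEOST", "CETACEAN", "hoenig_z", "compare_mortality"]


@dataclass(frozen=True)
class HoenigCoefficients:
    """Log-log regression coefficients ``ln Z = a + b ln(T_max)``."""

    taxon: str
    a: float
    b: float

    def __post_init__(self) -> None:
        if self.b >= 0:
            raise ValueError("slope b must be negative (mortality falls with longevity)")


TELEOST = HoenigCoefficients(taxon="teleost", a=1.46, b=-1.01)
CETACEAN = HoenigCoefficients(taxon="cetacean", a=0.941, b=-0.873)


def hoenig_z(t_max: float, coef: HoenigCoefficients = TELEOST) -> float:
    """Total instantaneous mortality (per year) from maximum age (years)."""
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    return float(np.exp(coef.a + coef.b * np.log(t_max)))


def compare_mortality(
    phi: float, indirect: Sequence[tuple[str, float]] = ()
) -> pd.DataFrame:
    """Side-by-side direct (from survival) and indirect mortality estimates.

    ``indirect`` pairs a label with a Hoenig ``Z`` value.  Indirect rows are
    flagged as resting on the Z = M assumption (valid only when unfished).
    """
    annual, z = survival_to_mortality(phi)
    rows = [
        {"estimate": "annual mortality 1-phi", "value": annual, "assumes_Z_eq_M": False},
        {"estimate": "instantaneous -ln(phi)", "value": z, "assumes_Z_eq_M": False},
    ]
    for label, zval in indirect:
        rows.append({"estimate": f"Hoenig Z ({label})", "value": zval, "assumes_Z_eq_M": True})
    return pd.DataFrame(rows)
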