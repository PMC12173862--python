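"""Scenario projection of dietary-health indices under aging and income growth.

The elderly share and per-capita income evolve by annual growth rates
(``ratio_t = ratio_{t-1} (1+m)``, ``income_t = income_{t-1} (1+n)``); each
index is then the unconstrained linear extrapolation
``y_t = alpha + beta3 * ratio_t + gamma * income_t`` with coefficients taken
from a fitted regression (or supplied directly).

Two driver modes are provided: ``multiplicative`` (the geometric recursion
above) and ``linear-increment`` (the rate applied as an annual
percentage-point / absolute increment), because a "1.03% per year" aging
rate reads either way and the two diverge substantially by 2050 (~26% vs
~48% elderly from a 20% start).  Neither is endorsed; both are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INDEX_RANGES = {"EI": (0.0, float(np.log(12.0))), "CFPS": (0.0, 8.0), "CHEI": (0.0, 60.0)}

#: Default scenario income growth rates: none / low 2.5% / medium 5% / high 7.5%.
DEFAULT_GROWTH_RATES = (0.0, 0.025, 0.05, 0.075)


@dataclass(frozen=True)
class IndexCoefficients:
    """(alpha, beta3, gamma): constant, elderly-share slope (per percentage
    point) and income slope (per 10^4 Yuan) for one index."""

    alpha: float
    beta3: float
    gamma: float


@dataclass(frozen=True)
class Scenario:
    """One aging-plus-income-growth trajectory.

    ``m`` is the annual aging growth rate (e.g. 0.0103), ``n`` the annual
    income growth rate; ``ratio_0`` is the elderly share (%) and
    ``income_0`` per-capita income (10^4 Yuan) in ``start_year``.
    """

    start_year: int = 2023
    end_year: int = 2050
    ratio_0: float = 26.61
    m: float = 0.0103
    income_0: float = 2.53
    n: float = 0.05
    growth_mode: str = "multiplicative"  # or "linear-increment"

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise ValueError("end_year must be >= start_year")
        if not (0 <= self.ratio_0 <= 100):
            raise ValueError("ratio_0 must lie in [0, 100]")
        if self.income_0 < 0:
            raise ValueError("income_0 must be non-negative")
        if self.growth_mode not in ("multiplicative", "linear-increment"):
            raise ValueError(f"unknown growth_mode {self.growth_mode!r}")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)


def project_drivers(scn: Scenario) -> tuple[np.ndarray, np.ndarray]:
    """Yearly elderly-share (%) and income (10^4 Yuan) series.

    Multiplicative mode compounds geometrically; linear-increment mode adds
    ``m`` percentage points (x100) of share and fraction ``n`` of the start
    income each year.  The share is clipped at 100% with a warning.
    """
    t = np.arange(scn.end_year - scn.start_year + 1)
    if scn.growth_mode == "multiplicative":
        ratio = scn.ratio_0 * (1.0 + scn.m) ** t
        income = scn.income_0 * (1.0 + scn.n) ** t
    else:
        ratio = scn.ratio_0 + 100.0 * scn.m * t
        income = scn.income_0 * (1.0 + scn.n * t)
    if (ratio > 100).any():
        logger.warning("projected elderly share exceeds 100%%; clipping")
        ratio = np.minimum(ratio, 100.0)
    return ratio, income


def project_index(
    coeffs: Mapping[str, IndexCoefficients],
    scn: Scenario,
    clip: bool = False,
) -> pd.DataFrame:
    """Yearly index trajectories: y_t = alpha + beta3 ratio_t + gamma income_t.

    ``clip=True`` restricts each index to its admissible range
    (EI to [0, ln 12], CFPS to [0, 8], CHEI to [0, 60]); off by default since
    the model is an unconstrained linear extrapolation.
    """
    if not coeffs:
        raise ValueError("no index coefficients supplied")
    ratio, income = project_drivers(scn)
    out = pd.DataFrame({"year": scn.years, "ratio": ratio, "income": income})
    for name, c in coeffs.items():
        y = c.alpha + c.beta3 * ratio + c.gamma * income
        if clip and name in INDEX_RANGES:
            lo, hi = INDEX_RANGES[name]
            y = np.clip(y, lo, hi)
        out[name] = y
    return out


def scenario_grid(
    coeffs: Mapping[str, IndexCoefficients],
    base: Scenario,
    n_values: Sequence[float] = DEFAULT_GROWTH_RATES,
    clip: bool = False,
) -> pd.DataFrame:
    """One trajectory per income growth rate, sharing the aging path.

    Terminal index values are monotone in the growth rate whenever the
    income coefficient gamma is positive (reversed for negative gamma).
    """
    if len(n_values) == 0:
        raise ValueError("n_values must be non-empty")
    frames = []
    for n in n_values:
        scn = Scenario(
            start_year=base.start_year, end_year=base.end_year,
            ratio_0=base.ratio_0, m=base.m, income_0=base.income_0,
            n=n, growth_mode=base.growth_mode,
        )
        df = project_index(coeffs, scn, clip=clip)
        df.insert(1, "scenario", f"n={n:g}")
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def coefficients_from_fit(fit, ratio_term: str = "ratio_over65",
                          income_term: str = "income") -> IndexCoefficients:
    """Extract (alpha, beta3, gamma) from a RegressionFit's parameter vector."""
    p = fit.params
    for term in ("const", ratio_term, income_term):
        if term not in p.index:
            raise ValueError(f"fit lacks required coefficient {term!r}")
    return IndexCoefficients(
        alpha=float(p["const"]), beta3=float(p[ratio_term]), gamma=float(p[income_term])
    )
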