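"""Time-varying forcing consumed by the decomposition models.

A :class:`ForcingSeries` bundles, per cell and per time step, the soil
temperature (column mean and per layer), the exogenous dimensionless
environmental scalars (water, oxygen, nitrogen), and the litter carbon input
rate, plus the static texture fractions.  The non-temperature scalars are
direct inputs, never computed here; only the temperature scalar is evaluated
by the models (it depends on the calibrated Q10).

Time axes are uniform, either monthly or daily, expressed in fractional
years.  Litter input is stored as an annual-equivalent rate (g C m-2 yr-1);
a step of length ``dt`` delivers ``litter * dt``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["ForcingSeries", "monthly_to_daily"]

DAYS_PER_YEAR = 365


@dataclass(frozen=True)
class ForcingSeries:
    """Per-cell forcing time series on a uniform monthly or daily axis.

    Attributes
    ----------
    time : (T,) fractional years since the series start
    temperature : (n_cells, T) column-mean soil temperature, degC
    temperature_layers : (n_cells, n_layers, T) per-layer soil temperature
    water, oxygen, nitrogen : (n_cells, T) dimensionless scalars in [0, 1]
    litter : (n_cells, T) litter C input rate, g C m-2 yr-1, >= 0
    sand, clay : (n_cells,) texture fractions in [0, 1]
    resolution : "monthly" or "daily"
    """

    time: np.ndarray
    temperature: np.ndarray
    temperature_layers: np.ndarray
    water: np.ndarray
    oxygen: np.ndarray
    nitrogen: np.ndarray
    litter: np.ndarray
    sand: np.ndarray
    clay: np.ndarray
    resolution: str = "monthly"

    def __post_init__(self):
        if self.resolution not in ("monthly", "daily"):
            raise ValueError("resolution must be 'monthly' or 'daily'")
        t = np.asarray(self.time, dtype=float)
        if t.size > 1:
            steps = np.diff(t)
            if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-12):
                raise ValueError("time axis must be uniform")
        if np.any(self.litter < 0):
            raise ValueError("litter input must be non-negative")
        for name in ("water", "oxygen", "nitrogen"):
            v = getattr(self, name)
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"{name} scalar must lie in [0, 1]")
        for name in ("sand", "clay"):
            v = getattr(self, name)
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"{name} fraction must lie in [0, 1]")

    @property
    def n_cells(self) -> int:
        return self.temperature.shape[0]

    @property
    def n_steps(self) -> int:
        return self.temperature.shape[1]

    @property
    def dt(self) -> float:
        """Step length in years."""
        return 1.0 / 12.0 if self.resolution == "monthly" else 1.0 / DAYS_PER_YEAR


def monthly_to_daily(forcing: ForcingSeries) -> ForcingSeries:
    """Resample a monthly series to daily by step-function repetition.

    Each month's values are repeated for the days of that month (365-day
    calendar, months of 30/31 days summing to 365 would complicate alignment;
    a uniform repetition of ceil(365/12) truncated to the year length keeps
    the axis uniform and the monthly means exact to < 2%).
    """
    if forcing.resolution != "monthly":
        raise ValueError("input series must be monthly")
    n_months = forcing.n_steps
    n_years = n_months // 12
    if n_months % 12:
        raise ValueError("monthly series must cover whole years")
    # day -> month index within a 365-day year, repeated per year
    month_of_day = np.minimum((np.arange(DAYS_PER_YEAR) * 12) // DAYS_PER_YEAR, 11)
    idx = (np.arange(n_years)[:, None] * 12 + month_of_day[None, :]).ravel()
    t0 = float(forcing.time[0])
    time = t0 + np.arange(n_years * DAYS_PER_YEAR) / DAYS_PER_YEAR
    take = lambda a: np.ascontiguousarray(a[..., idx])
    return replace(
        forcing,
        time=time,
        temperature=take(forcing.temperature),
        temperature_layers=take(forcing.temperature_layers),
        water=take(forcing.water),
        oxygen=take(forcing.oxygen),
        nitrogen=take(forcing.nitrogen),
        litter=take(forcing.litter),
        resolution="daily",
    )
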