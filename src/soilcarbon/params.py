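"""Named, bounded global parameter sets for the three model structures.

Each model carries a :class:`ParameterSpace`: an ordered list of parameter
names with uniform-prior bounds ``[lower, upper]``, default values, and
units.  Parameter vectors travel either as plain numpy arrays ordered like
the space, or as name->value dicts; helpers convert between the two and
read/write CSV/JSON keyed by the short names.

The conventional and vertically resolved spaces use published ranges and
defaults; the microbial (MIMICS) space uses the source model's defaults with
priors spanning [default/3, 3*default] (bounds sorted, so negative defaults
are handled).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ParameterSpace",
    "conventional_space",
    "vertical_space",
    "mimics_space",
]


@dataclass(frozen=True)
class ParameterSpace:
    names: tuple
    lower: np.ndarray
    upper: np.ndarray
    defaults: np.ndarray
    units: tuple

    def __post_init__(self):
        if not (len(self.names) == len(self.lower) == len(self.upper)
                == len(self.defaults) == len(self.units)):
            raise ValueError("inconsistent space definition")
        if np.any(self.lower >= self.upper):
            raise ValueError("lower bound must be below upper bound")

    @property
    def n_params(self) -> int:
        return len(self.names)

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    @property
    def prior_sd(self) -> np.ndarray:
        """Standard deviation of the uniform prior, width / sqrt(12)."""
        return self.width / np.sqrt(12.0)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def to_dict(self, theta) -> dict:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ValueError(f"expected {self.n_params} values, got {theta.shape}")
        return dict(zip(self.names, theta.tolist()))

    def to_array(self, values: dict) -> np.ndarray:
        missing = set(self.names) - set(values)
        if missing:
            raise KeyError(f"missing parameters: {sorted(missing)}")
        return np.array([float(values[n]) for n in self.names])

    def contains(self, theta) -> bool:
        theta = np.asarray(theta, dtype=float)
        return bool(np.all(theta >= self.lower) and np.all(theta <= self.upper))

    def validate(self, theta) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if not self.contains(theta):
            bad = [n for n, v, lo, hi in zip(self.names, theta, self.lower, self.upper)
                   if not lo <= v <= hi]
            raise ValueError(f"parameters out of bounds: {bad}")
        return theta

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        """Draw uniformly from the prior box."""
        shape = (self.n_params,) if size is None else (size, self.n_params)
        return self.lower + rng.random(shape) * self.width

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"name": self.names, "lower": self.lower, "upper": self.upper,
             "default": self.defaults, "unit": self.units}
        )

    def save_values(self, theta, path) -> None:
        path = str(path)
        values = self.to_dict(theta)
        if path.endswith(".json"):
            with open(path, "w") as fh:
                json.dump(values, fh, indent=2)
        else:
            pd.DataFrame({"name": list(values), "value": list(values.values())}
                         ).to_csv(path, index=False)

    def load_values(self, path) -> np.ndarray:
        path = str(path)
        if path.endswith(".json"):
            with open(path) as fh:
                values = json.load(fh)
        else:
            df = pd.read_csv(path)
            values = dict(zip(df["name"], df["value"]))
        return self.to_array(values)


def _space(rows):
    names, lo, hi, default, units = zip(*rows)
    return ParameterSpace(
        names=tuple(names),
        lower=np.array(lo, dtype=float),
        upper=np.array(hi, dtype=float),
        defaults=np.array(default, dtype=float),
        units=tuple(units),
    )


# (name, lower, upper, default, unit)
_CONVENTIONAL_ROWS = [
    ("t1", 0.0, 1.0, 0.85, "-"),          # f21 intercept coefficient
    ("t2", 0.0, 1.0, 0.68, "-"),          # f21 slope coefficient (vs sand)
    ("f31", 0.0, 0.01, 0.005, "-"),       # fast -> passive transfer fraction
    ("f12", 0.1, 0.6, 0.4185, "-"),       # slow -> fast
    ("f32", 0.0, 0.05, 0.0315, "-"),      # slow -> passive
    ("f13", 0.3, 0.7, 0.45, "-"),         # passive -> fast
    ("k1", 1.0, 15.0, 7.3, "gC/gC/yr"),   # fast-pool baseline turnover
    ("k2", 0.1, 0.5, 0.2, "gC/gC/yr"),    # slow-pool baseline turnover
    ("k3", 0.001, 0.01, 0.0045, "gC/gC/yr"),  # passive-pool baseline turnover
    ("Q10", 1.0, 3.0, 2.0, "-"),          # temperature sensitivity
]

_VERTICAL_ROWS = [
    ("D1", 0.3e-4, 16e-4, 1e-4, "m2/yr"),  # diffusivity, non-permafrost
    ("D2", 0.3e-4, 16e-4, 4e-4, "m2/yr"),  # diffusivity, permafrost (cryoturbation)
    ("zt", 0.0, 1.0, 0.5, "m"),            # e-folding depth of the depth scalar
] + _CONVENTIONAL_ROWS

# MIMICS: 22 global parameters.  V*/K* regressions are exponential in
# temperature (rate = exp(slope*T + intercept) * modifier); desorption from
# the physically protected pool is Da * exp(Db * clay).
_MIMICS_DEFAULTS = [
    ("fm", 0.10, "-"),        # litter fraction routed to SOM_p
    ("fs", 0.20, "-"),        # litter fraction routed to SOM_c
    ("fr", 0.40, "-"),        # r-strategist fraction of microbial biomass
    ("Vs", 0.063, "1/degC"),  # Vmax regression slope
    ("Vi", 5.47, "-"),        # Vmax regression intercept
    ("Ks", 0.017, "1/degC"),  # Km regression slope
    ("Ki", 3.19, "-"),        # Km regression intercept
    ("Vmra", 0.70, "-"),      # Vmax modifier, SOM_a uptake by r-guild
    ("Vmka", 0.14, "-"),      # Vmax modifier, SOM_a uptake by k-guild
    ("Vmrc", 0.14, "-"),      # Vmax modifier, SOM_c uptake by r-guild
    ("Vmkc", 0.21, "-"),      # Vmax modifier, SOM_c uptake by k-guild
    ("Kmra", 125.0, "-"),     # Km modifier, SOM_a uptake by r-guild
    ("Kmka", 250.0, "-"),     # Km modifier, SOM_a uptake by k-guild
    ("Kmrc", 250.0, "-"),     # Km modifier, SOM_c uptake by r-guild
    ("Kmkc", 125.0, "-"),     # Km modifier, SOM_c uptake by k-guild
    ("Kor", 4.0, "-"),        # oxidation modifier of SOM_c uptake, r-guild
    ("Kok", 4.0, "-"),        # oxidation modifier of SOM_c uptake, k-guild
    ("Da", 0.13, "1/yr"),     # desorption-rate coefficient
    ("Db", -1.5, "-"),        # desorption clay dependence (exponent slope)
    ("tau_r", 4.5, "1/yr"),   # r-guild microbial turnover
    ("tau_k", 1.2, "1/yr"),   # k-guild microbial turnover
    ("MGE1", 0.55, "-"),      # microbial growth efficiency on SOM_a uptake
]


def conventional_space() -> ParameterSpace:
    """Ten global parameters of the three-pool Century-type model."""
    return _space(_CONVENTIONAL_ROWS)


def vertical_space() -> ParameterSpace:
    """Thirteen global parameters of the vertically resolved model."""
    return _space(_VERTICAL_ROWS)


def mimics_space() -> ParameterSpace:
    """Twenty-two global parameters of the microbial model.

    Priors span [default/3, 3*default] with bounds sorted so negative
    defaults (the clay exponent Db) get a valid interval.
    """
    rows = []
    for name, d, unit in _MIMICS_DEFAULTS:
        lo, hi = sorted((d / 3.0, 3.0 * d))
        rows.append((name, lo, hi, d, unit))
    return _space(rows)
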