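"""Spatial grid, soil column discretization, and environmental scalars.

The working grid is an unstructured list of land cells, each carrying a
latitude/longitude, an area, and a permafrost flag.  The soil column is a
10-layer vertical discretization (depth positive downward, zero at the
surface; depth intervals are half-open ``[top, bottom)``).  Environmental
rate modifiers (temperature, moisture, oxygen, nitrogen, depth) are
dimensionless multipliers on baseline turnover; only the temperature scalar
is computed here — the others are exogenous forcing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Grid",
    "SoilColumn",
    "column_layout",
    "temperature_scalar",
    "env_modifier",
]

N_LAYERS = 10

T_REF = 25.0  # reference temperature (degC) at which the Q10 scalar equals 1


@dataclass(frozen=True)
class Grid:
    """Static per-cell attributes of the working grid.

    Parameters
    ----------
    cell_ids : array of int
        Unique cell identifiers.
    latitude, longitude : arrays of float
        Cell-center coordinates in degrees.
    area : array of float
        Cell area in m**2; strictly positive.
    land : boolean array
        Land mask.
    permafrost : boolean array
        Permafrost mask; a permafrost cell must be a land cell.
    """

    cell_ids: np.ndarray
    latitude: np.ndarray
    longitude: np.ndarray
    area: np.ndarray
    land: np.ndarray
    permafrost: np.ndarray

    def __post_init__(self):
        n = len(self.cell_ids)
        for name in ("latitude", "longitude", "area", "land", "permafrost"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have length {n}")
        if np.any(np.asarray(self.area) <= 0):
            raise ValueError("cell areas must be strictly positive")
        if np.any(np.asarray(self.permafrost) & ~np.asarray(self.land)):
            raise ValueError("permafrost cells must be land cells")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass(frozen=True)
class SoilColumn:
    """10-layer vertical discretization of the soil column.

    ``thickness`` is the prescribed layer thickness (m); interface depths are
    its cumulative sums and node depths sit at layer midpoints.
    """

    thickness: np.ndarray
    interfaces: np.ndarray = field(init=False)
    nodes: np.ndarray = field(init=False)

    def __post_init__(self):
        dz = np.asarray(self.thickness, dtype=float)
        if dz.shape != (N_LAYERS,):
            raise ValueError(f"expected {N_LAYERS} layer thicknesses, got {dz.shape}")
        if np.any(dz <= 0):
            raise ValueError("layer thicknesses must be positive")
        object.__setattr__(self, "thickness", dz)
        interfaces = np.cumsum(dz)
        tops = np.concatenate([[0.0], interfaces[:-1]])
        object.__setattr__(self, "interfaces", interfaces)
        object.__setattr__(self, "nodes", tops + dz / 2.0)

    @property
    def n_layers(self) -> int:
        return N_LAYERS

    @property
    def total_depth(self) -> float:
        return float(self.interfaces[-1])

    def layer_overlap(self, top: float, bottom: float) -> np.ndarray:
        """Thickness fraction of each layer inside the interval [top, bottom).

        Partially covered layers are pro-rated by the overlapping thickness.
        """
        if bottom <= top:
            raise ValueError("interval bottom must exceed top")
        tops = self.interfaces - self.thickness
        lo = np.maximum(tops, top)
        hi = np.minimum(self.interfaces, bottom)
        return np.clip(hi - lo, 0.0, None) / self.thickness


def column_layout(thicknesses=None) -> SoilColumn:
    """Build the soil column, defaulting to an exponential 10-layer scheme.

    The default mirrors the CLM-style discretization with interface depths
    ``0.025 * (exp(0.5 * i) - 1)`` for i = 1..10: thin layers near the surface
    growing exponentially with depth, total depth ~3.7 m (covers the 0-3 m
    observation aggregation range).
    """
    if thicknesses is None:
        i = np.arange(1, N_LAYERS + 1)
        interfaces = 0.025 * (np.exp(0.5 * i) - 1.0)
        thicknesses = np.diff(np.concatenate([[0.0], interfaces]))
    return SoilColumn(np.asarray(thicknesses, dtype=float))


def temperature_scalar(q10, t_soil):
    """Q10 temperature modifier of decomposition, ``Q10**((T - 25)/10)``.

    Equals 1 at 25 degC for any Q10; monotone increasing in temperature when
    Q10 > 1.  ``q10`` must be strictly positive.
    """
    q10 = np.asarray(q10, dtype=float)
    if np.any(q10 <= 0):
        raise ValueError("Q10 must be strictly positive")
    return q10 ** ((np.asarray(t_soil, dtype=float) - T_REF) / 10.0)


def env_modifier(*scalars):
    """Product of environmental scalars (temperature, water, oxygen, ...).

    Commutative and associative by construction; any zero scalar gives zero.
    All inputs must be non-negative.
    """
    if not scalars:
        raise ValueError("at least one scalar is required")
    out = np.asarray(scalars[0], dtype=float)
    if np.any(out < 0):
        raise ValueError("scalars must be non-negative")
    for s in scalars[1:]:
        s = np.asarray(s, dtype=float)
        if np.any(s < 0):
            raise ValueError("scalars must be non-negative")
        out = out * s
    return out
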