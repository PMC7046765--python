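"""Cell-density priors on the real (target) scale.

The measure-preserving transform needs the distribution of cells on the
scale of interest.  Two analytic priors cover the applications shipped
here, plus an empirical fallback:

* :class:`AgePrior` — the steady-state age distribution of an unperturbed
  exponentially growing population, ``p_a(a) = 2 gamma exp(-gamma a)`` on
  ``[0, T]`` with growth rate ``gamma = ln2 / T``.  Assumes no cell death
  and homogeneous cycle progression.
* :class:`SpheroidPrior` — the shell-volume distribution of a radially
  symmetric spheroid of radius ``r`` (um) with a necrotic core of radius
  ``r_N = max(r - d_N, 0)``: the cumulative fraction of viable cells
  within depth ``x`` of the surface is
  ``P_X(x) = (r^3 - (r-x)^3) / (r^3 - r_N^3)``.
* :class:`EmpiricalPrior` — a user-supplied tabulated CDF with monotone
  interpolation.

All priors expose ``pdf``, ``cdf`` and ``invcdf`` plus a ``support``
tuple; the linear :class:`GrowthModel` (radius in um vs. days since
seeding) converts spheroid age to radius.

Units: hours for cell age, days for spheroid growth, micrometres for
depth and radius.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = [
    "RealScalePrior",
    "AgePrior",
    "SpheroidPrior",
    "GrowthModel",
    "EmpiricalPrior",
    "age_pdf",
    "age_cdf",
    "age_invcdf",
    "spheroid_pdf",
    "spheroid_cdf",
    "spheroid_invcdf",
    "growth_radius",
    "fit_growth_model",
    "empirical_prior",
    "prior_from_config",
]

LN2 = math.log(2.0)


class RealScalePrior:
    """Interface: a prior exposes pdf, cdf, invcdf and a support interval."""

    #: (low, high) bounds of the scale
    support: tuple[float, float]
    #: unit of the scale, carried in metadata
    unit: str = ""

    def pdf(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def cdf(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def invcdf(self, u):  # pragma: no cover - interface
        raise NotImplementedError


def _check_range(x, lo, hi, name):
    x = np.asarray(x, dtype=float)
    if np.any((x < lo - 1e-12) | (x > hi + 1e-12)):
        raise ValueError(f"{name} outside [{lo:g}, {hi:g}]")
    return np.clip(x, lo, hi)


@dataclasses.dataclass(frozen=True)
class AgePrior(RealScalePrior):
    """Steady-state age distribution for cell-cycle length ``T`` (hours).

    In an unperturbed exponentially growing population the density of
    times-since-division is ``2 gamma exp(-gamma a)`` on ``[0, T]``, with
    ``gamma = ln2 / T``: newborn cells are exactly twice as dense as
    dividing ones.
    """

    T: float
    unit: str = "hours"

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ValueError("cell-cycle length T must be positive")

    @property
    def gamma(self) -> float:
        """Population growth rate ln2 / T (1/hours)."""
        return LN2 / self.T

    @property
    def support(self) -> tuple[float, float]:
        return (0.0, self.T)

    def pdf(self, a):
        a = _check_range(a, 0.0, self.T, "age")
        return 2.0 * self.gamma * np.exp(-self.gamma * a)

    def cdf(self, a):
        a = _check_range(a, 0.0, self.T, "age")
        return 2.0 * (1.0 - np.exp(-self.gamma * a))

    def invcdf(self, u):
        u = _check_range(u, 0.0, 1.0, "probability")
        return -np.log(1.0 - u / 2.0) / self.gamma


def age_pdf(a, prior: AgePrior):
    """Density 2*gamma*exp(-gamma*a) of the steady-state age law."""
    return prior.pdf(a)


def age_cdf(a, prior: AgePrior):
    return prior.cdf(a)


def age_invcdf(u, prior: AgePrior):
    return prior.invcdf(u)


@dataclasses.dataclass(frozen=True)
class SpheroidPrior(RealScalePrior):
    """Shell-volume depth distribution of a radially symmetric spheroid.

    Parameters
    ----------
    r
        Spheroid radius (um).
    d_N
        Depth from the surface at which necrosis begins (um).  The
        necrotic-core radius is ``r_N = max(r - d_N, 0)``; viable cells
        occupy depths ``[0, r - r_N]``.
    r_N_override
        Fix the necrotic-core radius directly instead of deriving it from
        ``d_N`` (must satisfy ``0 <= r_N < r``).
    """

    r: float
    d_N: float = math.inf
    r_N_override: float | None = None
    unit: str = "um"

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError("spheroid radius must be positive")
        if self.r_N_override is None and not self.d_N > 0:
            raise ValueError("necrosis depth d_N must be positive")
        rn = self.r_N
        if not (0.0 <= rn < self.r):
            raise ValueError(f"necrotic-core radius {rn:g} must lie in [0, r)")

    @property
    def r_N(self) -> float:
        """Necrotic-core radius (um)."""
        if self.r_N_override is not None:
            return self.r_N_override
        return max(self.r - self.d_N, 0.0)

    @property
    def support(self) -> tuple[float, float]:
        return (0.0, self.r - self.r_N)

    def _vol_norm(self) -> float:
        return self.r**3 - self.r_N**3

    def pdf(self, x):
        x = _check_range(x, 0.0, self.r - self.r_N, "depth")
        return 3.0 * (self.r - x) ** 2 / self._vol_norm()

    def cdf(self, x):
        x = _check_range(x, 0.0, self.r - self.r_N, "depth")
        return (self.r**3 - (self.r - x) ** 3) / self._vol_norm()

    def invcdf(self, u):
        u = _check_range(u, 0.0, 1.0, "probability")
        return self.r - np.cbrt(u * (self.r_N**3 - self.r**3) + self.r**3)


def spheroid_pdf(x, prior: SpheroidPrior):
    """Depth density 3 (r-x)^2 / (r^3 - r_N^3) on the viable rim."""
    return prior.pdf(x)


def spheroid_cdf(x, prior: SpheroidPrior):
    """Normalized shell volume within depth x of the surface."""
    return prior.cdf(x)


def spheroid_invcdf(u, prior: SpheroidPrior):
    return prior.invcdf(u)


@dataclasses.dataclass(frozen=True)
class GrowthModel:
    """Linear radial growth of a spheroid: ``r(t) = intercept + slope * t``.

    ``t`` in days since seeding, radius in um.
    """

    intercept: float
    slope: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.intercept) and np.isfinite(self.slope)):
            raise ValueError("growth coefficients must be finite")

    def radius(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time since seeding must be non-negative")
        r = self.intercept + self.slope * t
        if np.any(r <= 0):
            raise ValueError("growth model predicts non-positive radius")
        return r


def growth_radius(t, model: GrowthModel):
    """Spheroid radius (um) at ``t`` days since seeding."""
    return model.radius(t)


def fit_growth_model(times, radii) -> GrowthModel:
    """Ordinary least-squares line through pooled (time, radius) points."""
    t = np.asarray(times, dtype=float).ravel()
    r = np.asarray(radii, dtype=float).ravel()
    if t.size != r.size:
        raise ValueError("times and radii must have equal length")
    if t.size < 2 or np.ptp(t) == 0:
        raise ValueError("need at least 2 distinct time points")
    A = np.column_stack([np.ones_like(t), t])
    (intercept, slope), *_ = np.linalg.lstsq(A, r, rcond=None)
    return GrowthModel(intercept=float(intercept), slope=float(slope))


class EmpiricalPrior(RealScalePrior):
    """A tabulated CDF on the real scale, interpolated monotonically.

    Flat CDF segments (zero-density gaps) are handled with the
    left-continuous pseudo-inverse: ``invcdf(u)`` returns the smallest
    grid position attaining cumulative mass ``u``.
    """

    def __init__(self, grid, cdf, unit: str = ""):
        grid = np.asarray(grid, dtype=float)
        cdf = np.asarray(cdf, dtype=float)
        if grid.shape != cdf.shape or grid.ndim != 1 or grid.size < 2:
            raise ValueError("grid and cdf must be 1-D arrays of equal length >= 2")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(np.diff(cdf) < 0):
            raise ValueError("cdf values must be nondecreasing")
        if abs(cdf[0]) > 1e-9 or abs(cdf[-1] - 1.0) > 1e-9:
            raise ValueError("cdf must start at 0 and end at 1")
        self.grid = grid
        self._cdf = np.clip(cdf, 0.0, 1.0)
        self._cdf[0], self._cdf[-1] = 0.0, 1.0
        self._pdf = np.gradient(self._cdf, self.grid)
        self.unit = unit

    @property
    def support(self) -> tuple[float, float]:
        return (float(self.grid[0]), float(self.grid[-1]))

    def pdf(self, x):
        x = _check_range(x, *self.support, "position")
        return np.interp(x, self.grid, self._pdf)

    def cdf(self, x):
        x = _check_range(x, *self.support, "position")
        return np.interp(x, self.grid, self._cdf)

    def invcdf(self, u):
        u = _check_range(u, 0.0, 1.0, "probability")
        # left-continuous pseudo-inverse: first grid point reaching mass u
        idx = np.searchsorted(self._cdf, u, side="left")
        idx = np.clip(idx, 1, self.grid.size - 1)
        c0, c1 = self._cdf[idx - 1], self._cdf[idx]
        g0, g1 = self.grid[idx - 1], self.grid[idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(c1 > c0, (u - c0) / (c1 - c0), 0.0)
        out = g0 + frac * (g1 - g0)
        return out if np.ndim(u) else float(out)


def empirical_prior(grid, cdf_values, unit: str = "") -> EmpiricalPrior:
    """Build an :class:`EmpiricalPrior` from tabulated CDF values."""
    return EmpiricalPrior(grid, cdf_values, unit=unit)


def prior_from_config(cfg: dict) -> RealScalePrior:
    """Instantiate a prior from a config mapping.

    Supported ``type`` values::

        {type: age, T: <hours>}
        {type: spheroid, r: <um>, d_N: <um>}            # or r_N: <um>
        {type: spheroid_from_growth, seed_day: <days>, d_N: <um>,
         growth: {intercept: <um>, slope: <um/day>}}
        {type: empirical, file: <csv with x,cdf columns>}
    """
    if "type" not in cfg:
        raise ValueError("prior config needs a 'type' key")
    kind = cfg["type"]
    if kind == "age":
        return AgePrior(T=float(cfg["T"]))
    if kind == "spheroid":
        if "r_N" in cfg:
            return SpheroidPrior(r=float(cfg["r"]), r_N_override=float(cfg["r_N"]))
        return SpheroidPrior(r=float(cfg["r"]), d_N=float(cfg.get("d_N", math.inf)))
    if kind == "spheroid_from_growth":
        g = cfg["growth"]
        model = GrowthModel(intercept=float(g["intercept"]), slope=float(g["slope"]))
        r = float(model.radius(float(cfg["seed_day"])))
        return SpheroidPrior(r=r, d_N=float(cfg.get("d_N", math.inf)))
    if kind == "empirical":
        import pandas as pd

        tab = pd.read_csv(cfg["file"], comment="#")
        return EmpiricalPrior(tab.iloc[:, 0].to_numpy(), tab.iloc[:, 1].to_numpy())
    raise ValueError(f"unknown prior type {kind!r}")
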