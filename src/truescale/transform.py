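"""The measure-preserving map from pseudotime to a real scale.

Given the cell density ``p_s`` on pseudotime and a prior for the cell
density ``p_x`` on the target scale (age, depth, or empirical), the
monotone map

    tau(s) = P_x^{-1}( P_s(s) )

matches cumulative mass on the two scales: the fraction of cells before
pseudotime ``s`` equals the fraction before position ``tau(s)``.  Pushing
densities through ``tau`` uses the change of variables

    p_x(x) = |d tau^{-1}(x) / dx| * p_s(tau^{-1}(x)),

and the same Jacobian factor carries joint densities ``p_s(s, y)`` to
``p_x(x, y)``.  Conditional marker densities ``p(y | x)`` and their
quantile summaries (median and confidence bands) are the typical read-out.

Numerics: ``P_s`` by cumulative trapezoidal integration of the KDE,
inversion by monotone interpolation; the Jacobian by central finite
differences with one-sided stencils at the ends.  Flat stretches of
``P_s`` (zero-density gaps) use the left-continuous pseudo-inverse and
emit a warning.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .densities import Density1D, JointDensity2D
from .priors import RealScalePrior

__all__ = [
    "TransformMap",
    "ConditionalDensity",
    "TrajectorySummary",
    "build_map",
    "transform_density",
    "transform_joint",
    "conditional_density",
    "trajectory_summary",
    "reconstruct_trajectory",
    "half_max_crossing",
    "normalize_to_surface_median",
]

#: x-columns whose marginal falls below this fraction of its maximum are
#: masked in conditional densities (too few cells for a reliable profile)
LOW_DENSITY_FRACTION = 0.01
#: cutoff (um) for surface-median intensity normalization in spheroids
SURFACE_NORM_CUTOFF_UM = 150.0


@dataclasses.dataclass
class TransformMap:
    """The monotone map ``tau`` between pseudotime and the real scale.

    ``s_grid`` and ``x_grid = tau(s_grid)`` tabulate the map; ``forward``
    and ``inverse`` interpolate monotonically between nodes.
    """

    s_grid: np.ndarray
    x_grid: np.ndarray
    source_cdf: np.ndarray  # P_s on s_grid
    prior: RealScalePrior | None = None

    def __post_init__(self) -> None:
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        self.x_grid = np.asarray(self.x_grid, dtype=float)
        if np.any(np.diff(self.x_grid) < 0) or np.any(np.diff(self.s_grid) < 0):
            raise ValueError("transform map must be nondecreasing")

    def forward(self, s):
        """tau(s): pseudotime -> real scale."""
        return np.interp(s, self.s_grid, self.x_grid)

    def inverse(self, x):
        """tau^{-1}(x): real scale -> pseudotime (left-continuous on flats)."""
        xg, idx = np.unique(self.x_grid, return_index=True)
        return np.interp(x, xg, self.s_grid[idx])

    def inverted(self) -> "TransformMap":
        """The map in the opposite direction (real scale -> pseudotime)."""
        xg, idx = np.unique(self.x_grid, return_index=True)
        return TransformMap(
            s_grid=xg,
            x_grid=self.s_grid[idx],
            source_cdf=self.source_cdf[idx],
            prior=None,
        )


@dataclasses.dataclass
class ConditionalDensity:
    """Columnwise-normalized marker density p(y | x).

    ``p[i, :]`` integrates to 1 over ``grid_y`` for every valid column;
    columns where the x-marginal carries too little mass are masked
    (``valid[i] = False``, ``p[i, :] = nan``) rather than NaN-propagated
    into downstream summaries.
    """

    grid_x: np.ndarray
    grid_y: np.ndarray
    p: np.ndarray
    valid: np.ndarray
    log_scale_y: bool = False


@dataclasses.dataclass
class TrajectorySummary:
    """Per-position marker quantiles: a median profile with bands."""

    grid_x: np.ndarray
    quantiles: tuple[float, ...]
    curves: np.ndarray  # (n_quantiles, n_x); nan where masked
    log_scale_y: bool = False

    @property
    def median(self) -> np.ndarray:
        i = int(np.argmin(np.abs(np.asarray(self.quantiles) - 0.5)))
        return self.curves[i]

    @property
    def lower(self) -> np.ndarray:
        return self.curves[0]

    @property
    def upper(self) -> np.ndarray:
        return self.curves[-1]


def build_map(p_s: Density1D, prior: RealScalePrior) -> TransformMap:
    """Compose the pseudotime CDF with the prior's inverse CDF.

    ``P_s`` is the cumulative trapezoidal integral of ``p_s`` (clipped to
    [0, 1] and renormalized); ``tau(s) = prior.invcdf(P_s(s))``.
    """
    cdf = p_s.cdf_values()
    if np.any(np.diff(cdf) <= 0):
        warnings.warn(
            "pseudotime density has zero-mass regions; "
            "using left-continuous pseudo-inverse on flat stretches",
            stacklevel=2,
        )
    x = np.asarray(prior.invcdf(cdf), dtype=float)
    x = np.maximum.accumulate(x)  # guard against round-off wiggles
    return TransformMap(s_grid=p_s.grid, x_grid=x, source_cdf=cdf, prior=prior)


def _jacobian_ds_dx(map: TransformMap) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """|d tau^{-1}/dx| on the deduplicated x-grid, by finite differences."""
    xg, idx = np.unique(map.x_grid, return_index=True)
    sg = map.s_grid[idx]
    if xg.size < 2:
        raise ValueError("transform map is degenerate (constant)")
    jac = np.gradient(sg, xg)
    return xg, sg, np.clip(jac, 0.0, None)


def transform_density(p_s: Density1D, map: TransformMap) -> Density1D:
    """Push a pseudotime density to the real scale (change of variables).

    When ``map`` was built from this same ``p_s`` the result equals the
    prior's pdf up to discretization — a useful self-consistency check.
    """
    xg, sg, jac = _jacobian_ds_dx(map)
    p = np.interp(sg, p_s.grid, p_s.p) * jac
    return Density1D(xg, p, kind="transformed", log_scale=p_s.log_scale)


def transform_joint(p_sy: JointDensity2D, map: TransformMap) -> JointDensity2D:
    """Push a joint (pseudotime, marker) density onto the real scale.

    Output rows sit at ``x = tau(s)`` for the deduplicated map nodes;
    each row of ``p_s(s, y)`` is scaled by the Jacobian ``|ds/dx|``.
    """
    xg, sg, jac = _jacobian_ds_dx(map)
    rows = np.empty((sg.size, p_sy.grid_y.size))
    for j, s in enumerate(sg):
        # interpolate along the s-axis of the joint density
        i = np.searchsorted(p_sy.grid_s, s, side="right") - 1
        i = np.clip(i, 0, p_sy.grid_s.size - 2)
        t = (s - p_sy.grid_s[i]) / (p_sy.grid_s[i + 1] - p_sy.grid_s[i])
        t = np.clip(t, 0.0, 1.0)
        rows[j] = (1.0 - t) * p_sy.p[i] + t * p_sy.p[i + 1]
    p = rows * jac[:, None]
    return JointDensity2D(xg, p_sy.grid_y, p, log_scale_y=p_sy.log_scale_y)


def conditional_density(p_xy: JointDensity2D) -> ConditionalDensity:
    """Normalize each x-column of a joint density over the marker axis.

    p(y | x) = p(x, y) / \\int p(x, y) dy.  Columns whose marginal mass is
    below ``LOW_DENSITY_FRACTION`` of the maximum — profile ends where few
    cells sit — are masked as missing.
    """
    marg = np.trapezoid(p_xy.p, p_xy.grid_y, axis=1)
    valid = marg > LOW_DENSITY_FRACTION * marg.max()
    p = np.full_like(p_xy.p, np.nan)
    p[valid] = p_xy.p[valid] / marg[valid, None]
    return ConditionalDensity(
        grid_x=p_xy.grid_s,
        grid_y=p_xy.grid_y,
        p=p,
        valid=valid,
        log_scale_y=p_xy.log_scale_y,
    )


def trajectory_summary(
    cond: ConditionalDensity,
    quantiles: tuple[float, ...] = (0.25, 0.5, 0.75),
) -> TrajectorySummary:
    """Quantile curves of p(y | x) via cumulative inversion per column."""
    from scipy.integrate import cumulative_trapezoid

    q = tuple(float(v) for v in quantiles)
    if any(not 0.0 < v < 1.0 for v in q) or list(q) != sorted(q):
        raise ValueError("quantiles must be sorted and strictly inside (0, 1)")
    curves = np.full((len(q), cond.grid_x.size), np.nan)
    for i in np.flatnonzero(cond.valid):
        c = cumulative_trapezoid(cond.p[i], cond.grid_y, initial=0.0)
        if c[-1] <= 0:
            continue
        c /= c[-1]
        # make strictly increasing for interpolation
        c = np.maximum.accumulate(c)
        curves[:, i] = np.interp(q, c, cond.grid_y)
    return TrajectorySummary(
        grid_x=cond.grid_x, quantiles=q, curves=curves, log_scale_y=cond.log_scale_y
    )


def reconstruct_trajectory(
    s: np.ndarray,
    y: np.ndarray,
    prior: RealScalePrior,
    boundary: str = "reflecting",
    log_y: bool = False,
    quantiles: tuple[float, ...] = (0.25, 0.5, 0.75),
    h_s: float | None = None,
    h_y: float | None = None,
):
    """Snapshot to real-scale trajectory in one call.

    Chains the standard stages: Silverman bandwidths, pseudotime KDE
    (reflecting or linked boundary), measure-preserving map from the
    prior, joint-density transform, conditional normalization and
    quantile summary.  Returns
    ``(p_s, map, joint_x, conditional, summary)``.
    """
    from . import densities as dens

    s = np.asarray(s, dtype=float)
    y = np.asarray(y, dtype=float)
    if h_s is None:
        h_s = dens.silverman_bandwidth(s)
    yk = np.log10(y) if log_y else y
    if h_y is None:
        h_y = dens.silverman_bandwidth(yk)
    kde = dens.kde_linked if boundary == "linked" else dens.kde_reflecting
    p_s = kde(s, h_s)
    tmap = build_map(p_s, prior)
    joint = dens.kde_joint(
        dens.PseudotimeSample(s=s, y=y),
        dens.Bandwidths(h_s, h_y),
        boundary=boundary,
        log_scale_y=log_y,
    )
    joint_x = transform_joint(joint, tmap)
    cond = conditional_density(joint_x)
    summ = trajectory_summary(cond, quantiles)
    return p_s, tmap, joint_x, cond, summ


def half_max_crossing(
    x: np.ndarray,
    profile: np.ndarray,
    low_region: float = 0.15,
    high_region: float = 0.3,
) -> float:
    """Position of the half-maximal rise of a low-to-high profile.

    Plateau levels are taken as medians over the first ``low_region``
    and last ``high_region`` fractions of the x-range (NaN entries
    ignored); the crossing of ``(low + high) / 2`` is located by linear
    interpolation at the first upward crossing.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(profile, dtype=float)
    ok = np.isfinite(m)
    xv, mv = x[ok], m[ok]
    if xv.size < 4:
        raise ValueError("profile too short for a half-max estimate")
    span = xv[-1] - xv[0]
    lo = np.median(mv[xv <= xv[0] + low_region * span])
    hi = np.median(mv[xv >= xv[-1] - high_region * span])
    half = 0.5 * (lo + hi)
    idx = np.flatnonzero((mv[:-1] < half) & (mv[1:] >= half))
    if idx.size == 0:
        raise ValueError("profile never crosses its half-maximal level")
    i = idx[0]
    return float(
        xv[i] + (half - mv[i]) * (xv[i + 1] - xv[i]) / (mv[i + 1] - mv[i])
    )


def normalize_to_surface_median(
    y: np.ndarray,
    depths: np.ndarray,
    cutoff: float = SURFACE_NORM_CUTOFF_UM,
) -> np.ndarray:
    """Divide each channel by its median over cells within ``cutoff`` of
    the surface.

    Spheroid intensities are reported relative to the rim population
    (default: cells up to 150 um deep), making profiles comparable across
    spheroid sizes and staining batches.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    y = np.asarray(y, dtype=float)
    depths = np.asarray(depths, dtype=float)
    rim = depths <= cutoff
    if not np.any(rim):
        raise ValueError(f"no cells within {cutoff:g} of the surface")
    med = np.median(y[rim], axis=0)
    if np.any(np.asarray(med) == 0):
        raise ValueError("surface median is zero for some channel")
    return y / med
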