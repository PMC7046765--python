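"""Calibration of live-cell reporter traces against a reconstructed density.

Time-lapse traces of a cell-cycle reporter (e.g. geminin) come in
arbitrary intensity units with an instrument background.  To compare them
with the snapshot-derived joint density ``p(x, y)`` on (time since
division, reporter intensity), a global background offset ``theta1`` and
scale factor ``theta2`` are fitted by maximizing

    sum_i sum_k log p( t_k, (y_i(t_k) - theta1) * theta2 )

over all cells ``i`` and trace time points ``k``, with ``p`` interpolated
bilinearly from the density grid.  Transformed values falling outside the
grid contribute a small floor density so the objective stays finite.

The optimizer is a derivative-free simplex (Nelder-Mead) with ``theta2``
parametrized on log scale to enforce positivity, restarted from three
perturbed initial points to mitigate local optima.  One global
``(theta1, theta2)`` pair is fitted by default; per-cell fitting is
available via :func:`fit_trace_scaling` with ``per_cell=True``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import minimize

from .densities import JointDensity2D

__all__ = [
    "TraceSet",
    "CalibrationResult",
    "trace_loglik",
    "fit_trace_scaling",
    "sample_traces_from_density",
]

#: density floor applied before taking logs (objective undefined at p=0)
DENSITY_FLOOR = 1e-12


@dataclasses.dataclass
class TraceSet:
    """Live-cell trajectories: per cell, times since division and intensities."""

    times: list[np.ndarray]
    values: list[np.ndarray]
    cell_ids: list | None = None

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise ValueError("times and values must list the same cells")
        if len(self.times) < 1:
            raise ValueError("need at least one trace")
        self.times = [np.asarray(t, dtype=float) for t in self.times]
        self.values = [np.asarray(v, dtype=float) for v in self.values]
        for t, v in zip(self.times, self.values):
            if t.shape != v.shape:
                raise ValueError("trace time and value arrays differ in length")
            if np.any(t < 0):
                raise ValueError("trace times must be non-negative")
            if np.any(np.diff(t) <= 0):
                raise ValueError("trace times must be strictly increasing")

    @property
    def n_cells(self) -> int:
        return len(self.times)

    @property
    def n_points(self) -> int:
        return int(sum(t.size for t in self.times))

    @classmethod
    def from_frame(cls, frame) -> "TraceSet":
        """Build from a long-format table with cell_id, t, y columns."""
        times, values, ids = [], [], []
        for cid, grp in frame.groupby("cell_id", sort=True):
            grp = grp.sort_values("t")
            times.append(grp["t"].to_numpy(dtype=float))
            values.append(grp["y"].to_numpy(dtype=float))
            ids.append(cid)
        return cls(times=times, values=values, cell_ids=ids)


@dataclasses.dataclass(frozen=True)
class CalibrationResult:
    """Fitted background offset and scale with the objective at optimum."""

    theta1: float
    theta2: float
    loglik: float
    converged: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        if not self.theta2 > 0:
            raise ValueError("scale factor theta2 must be positive")
        if not np.isfinite(self.loglik):
            raise ValueError("log-likelihood must be finite")


def sample_traces_from_density(
    cond,
    times: np.ndarray,
    n_traces: int,
    theta: tuple[float, float] = (0.0, 1.0),
    seed: int | np.random.Generator = 0,
) -> TraceSet:
    """Draw synthetic reporter traces from a conditional density.

    For each trace, a marker value is sampled at every time point from
    ``p(y | x = t)`` (nearest valid column, inverse-CDF draw); if the
    density's marker axis is log10 intensity the draws are exponentiated
    back to linear units.  The raw trace is then de-calibrated with the
    known ``theta = (theta1, theta2)``: ``y_raw = y / theta2 + theta1``,
    so a subsequent fit should recover ``theta``.
    """
    from scipy.integrate import cumulative_trapezoid

    rng = np.random.default_rng(seed)
    theta1, theta2 = theta
    times = np.asarray(times, dtype=float)
    valid_idx = np.flatnonzero(cond.valid)
    if valid_idx.size == 0:
        raise ValueError("conditional density has no valid columns")
    # precompute per-time-point column CDFs
    cols = []
    for tk in times:
        j = valid_idx[np.argmin(np.abs(cond.grid_x[valid_idx] - tk))]
        c = cumulative_trapezoid(cond.p[j], cond.grid_y, initial=0.0)
        c = np.maximum.accumulate(c / c[-1])
        cols.append(c)
    tlist, vlist = [], []
    for _ in range(n_traces):
        y = np.array([
            np.interp(rng.uniform(), c, cond.grid_y) for c in cols
        ])
        if cond.log_scale_y:
            y = 10.0**y
        tlist.append(times.copy())
        vlist.append(y / theta2 + theta1)
    return TraceSet(times=tlist, values=vlist)


def _interpolator(density: JointDensity2D) -> RegularGridInterpolator:
    return RegularGridInterpolator(
        (density.grid_s, density.grid_y),
        density.p,
        bounds_error=False,
        fill_value=0.0,
    )


def trace_loglik(
    traces: TraceSet,
    density: JointDensity2D,
    theta: tuple[float, float],
    log_y: bool | None = None,
    floor: float = DENSITY_FLOOR,
) -> float:
    """Log-likelihood of traces under the reconstructed joint density.

    ``theta = (theta1, theta2)``; each raw intensity is mapped to
    ``(y - theta1) * theta2`` before density lookup.  With ``log_y``
    (default: the density's own ``log_scale_y`` flag) the density's
    marker axis is log10 intensity, so the transformed value is
    log10-compressed first; non-positive transformed intensities fall to
    the floor.

    Raises
    ------
    ValueError
        If theta2 is not positive, or every contribution sits at the
        floor (no overlap between traces and density support).
    """
    theta1, theta2 = float(theta[0]), float(theta[1])
    if theta2 <= 0:
        raise ValueError("theta2 must be positive")
    if log_y is None:
        log_y = density.log_scale_y
    interp = _interpolator(density)

    total = 0.0
    any_inside = False
    for t, y in zip(traces.times, traces.values):
        z = (y - theta1) * theta2
        if log_y:
            ok = z > 0
            zt = np.where(ok, z, 1.0)
            z = np.where(ok, np.log10(zt), -np.inf)
        pts = np.column_stack([t, z])
        finite = np.isfinite(z)
        p = np.zeros(t.size)
        if np.any(finite):
            p[finite] = interp(pts[finite])
        inside = p > floor
        any_inside = any_inside or bool(np.any(inside))
        total += float(np.sum(np.log(np.maximum(p, floor))))
    if not any_inside:
        raise ValueError(
            "no overlap between transformed traces and the density support"
        )
    return total


def fit_trace_scaling(
    traces: TraceSet,
    density: JointDensity2D,
    init: tuple[float, float] = (0.0, 1.0),
    log_y: bool | None = None,
    per_cell: bool = False,
    n_starts: int = 3,
    seed: int | None = None,
) -> CalibrationResult | list[CalibrationResult]:
    """Maximize :func:`trace_loglik` over (theta1, theta2).

    Derivative-free Nelder-Mead on ``(theta1, log theta2)``; ``n_starts``
    perturbed restarts.  The returned optimum is never worse than the
    objective at ``init``.  With ``per_cell=True`` a separate pair is
    fitted for each trace and a list is returned.
    """
    if per_cell:
        return [
            fit_trace_scaling(
                TraceSet([t], [v]), density, init=init, log_y=log_y,
                per_cell=False, n_starts=n_starts, seed=seed,
            )
            for t, v in zip(traces.times, traces.values)
        ]

    theta1_0, theta2_0 = float(init[0]), float(init[1])
    if theta2_0 <= 0:
        raise ValueError("initial theta2 must be positive")
    rng = np.random.default_rng(seed)
    y_scale = max(
        float(np.median([np.median(np.abs(v)) for v in traces.values])), 1e-6
    )

    def objective(params: np.ndarray) -> float:
        th1, log_th2 = params
        if abs(log_th2) > 50:
            return np.inf
        try:
            return -trace_loglik(
                traces, density, (th1, np.exp(log_th2)), log_y=log_y
            )
        except ValueError:
            return np.inf

    x0 = np.array([theta1_0, np.log(theta2_0)])
    f0 = objective(x0)
    starts = [x0]
    # coarse pre-scan: the surface can hold local optima when the
    # background offset is mis-initialized.  The background must lie
    # below every trace value; candidate scales align the trace range
    # with the density's marker range.
    y_min = min(float(np.min(v)) for v in traces.values)
    y_max = max(float(np.max(v)) for v in traces.values)
    gy_hi = density.grid_y[-1]
    target_hi = 10.0**gy_hi if (log_y if log_y is not None else density.log_scale_y) else gy_hi
    cand_t1 = [theta1_0, 0.0, 0.5 * y_min, 0.9 * y_min, 0.99 * y_min]
    cand_t2 = [theta2_0]
    for t1 in (0.0, 0.9 * y_min):
        if y_max > t1:
            cand_t2.append(max(target_hi / (y_max - t1), 1e-9))
    grid_pts = sorted(
        ((objective(np.array([t1, np.log(t2)])), t1, np.log(t2))
         for t1 in cand_t1 for t2 in cand_t2 if t2 > 0),
        key=lambda z: z[0],
    )
    for f, t1, lt2 in grid_pts[:2]:
        if np.isfinite(f):
            starts.append(np.array([t1, lt2]))
    # wide random restarts on top of the scan
    for _ in range(max(n_starts - 1, 0)):
        starts.append(
            x0 + np.array([rng.normal(0.0, 0.3 * y_scale), rng.normal(0.0, 0.8)])
        )

    best_x, best_f, best_ok, msg = x0, f0, True, "initial point"
    for start in starts:
        res = minimize(
            objective, start, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
        )
        if res.fun < best_f:
            best_x, best_f, best_ok, msg = res.x, res.fun, bool(res.success), res.message
    return CalibrationResult(
        theta1=float(best_x[0]),
        theta2=float(np.exp(best_x[1])),
        loglik=float(-best_f),
        converged=best_ok,
        message=str(msg),
    )
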