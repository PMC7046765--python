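"""Synthetic single-cell populations with known ground truth.

Snapshot cytometry data with a known underlying scale is what every
stage of the pipeline is tested against.  Two populations are emulated:

* **Cell cycle** — an unsynchronised exponentially growing population.
  Ages (time since division, hours) are drawn from the steady-state age
  law by inverse-CDF sampling; DNA content runs 2N in G1, rises linearly
  through S, 4N in G2/M; a geminin-like reporter switches on at S-phase
  onset ``t_S``, rising rapidly (logistic in age, width ~0.75 h) from a
  background level to a ~100-fold plateau, so its intensity spans two
  decades as real reporters do.

* **Spheroid** — a radially symmetric spheroid.  Depths from the surface
  are drawn from the shell-volume law; a Ki-67-like proliferation marker
  and an RNA-like content decrease with depth, a p27-like quiescence
  marker increases, each as a logistic mean curve with a stored
  ground-truth midpoint.

All intensities carry multiplicative lognormal noise (default CV 0.15,
typical of fluorescence measurements).  Pseudotime stands in for an
external ordering algorithm: any strictly monotone distortion of the
true scale, min-max normalized to [0, 1] — real algorithms disagree in
their pseudotime *values* while largely conserving the cell *order*, and
that is exactly the invariance the transform must provide.

Every generator takes an explicit seed; there is no hidden global state.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .priors import AgePrior, GrowthModel, SpheroidPrior

__all__ = [
    "CellCycleParams",
    "SpheroidParams",
    "CellCyclePopulation",
    "SpheroidPopulation",
    "sample_ages",
    "simulate_cell_cycle_markers",
    "sample_depths",
    "simulate_spheroid_markers",
    "distort_to_pseudotime",
    "simulate_growth_series",
    "DISTORTIONS",
]

#: default lognormal noise coefficient of variation for intensities
DEFAULT_NOISE_CV = 0.15


def _lognormal_noise(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Multiplicative noise with unit median and coefficient of variation cv."""
    if cv < 0:
        raise ValueError("noise CV must be non-negative")
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return rng.lognormal(mean=0.0, sigma=sigma, size=n)


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclasses.dataclass(frozen=True)
class CellCycleParams:
    """Ground-truth parameters of the simulated cell-cycle population.

    Times in hours.  DNA content on the 2N..4N scale; the geminin-like
    reporter rises from ``gem_background`` to
    ``gem_background * (1 + gem_fold)`` around S-phase onset ``t_S`` with
    logistic width ``gem_rise_width``.
    """

    T: float = 20.0            # cell-cycle length
    t_S: float = 7.0           # S-phase onset (G1 duration)
    s_duration: float = 8.0    # S-phase duration; G2/M fills the rest
    gem_background: float = 1.0
    gem_fold: float = 99.0
    gem_rise_width: float = 0.75
    noise_cv: float = DEFAULT_NOISE_CV

    def __post_init__(self) -> None:
        if not 0 < self.t_S < self.T:
            raise ValueError("S-phase onset must lie inside the cycle")
        if self.t_S + self.s_duration >= self.T:
            raise ValueError("S phase must end before mitosis")
        if self.gem_rise_width <= 0 or self.gem_background <= 0:
            raise ValueError("reporter parameters must be positive")


@dataclasses.dataclass
class CellCyclePopulation:
    """A simulated unsynchronised population with known ages."""

    ages: np.ndarray
    dna: np.ndarray
    geminin: np.ndarray
    pseudotime: np.ndarray | None
    params: CellCycleParams

    def to_frame(self) -> pd.DataFrame:
        d = {
            "cell_id": np.arange(self.ages.size),
            "dna": self.dna,
            "geminin": self.geminin,
            "truth_age": self.ages,
        }
        if self.pseudotime is not None:
            d["s"] = self.pseudotime
        return pd.DataFrame(d)


@dataclasses.dataclass(frozen=True)
class SpheroidParams:
    """Ground-truth parameters of the simulated spheroid population.

    Depths in um.  Each marker follows a logistic mean curve in depth
    with midpoint ``m`` and width ``w``: Ki-67-like and RNA-like decrease
    from a high plateau, p27-like increases from a low one.
    """

    ki67_mid: float = 100.0
    ki67_width: float = 20.0
    ki67_high: float = 10.0
    ki67_low: float = 1.0
    p27_mid: float = 150.0
    p27_width: float = 25.0
    p27_high: float = 8.0
    p27_low: float = 1.0
    rna_mid: float = 120.0
    rna_width: float = 30.0
    rna_high: float = 12.0
    rna_low: float = 2.0
    noise_cv: float = DEFAULT_NOISE_CV

    def __post_init__(self) -> None:
        for name in ("ki67", "p27", "rna"):
            if getattr(self, f"{name}_width") <= 0:
                raise ValueError(f"{name} logistic width must be positive")
            if getattr(self, f"{name}_high") <= getattr(self, f"{name}_low"):
                raise ValueError(f"{name} high plateau must exceed low plateau")


@dataclasses.dataclass
class SpheroidPopulation:
    """A simulated dissociated spheroid with known cell depths."""

    depths: np.ndarray
    ki67: np.ndarray
    p27: np.ndarray
    rna: np.ndarray
    pseudotime: np.ndarray | None
    params: SpheroidParams

    def to_frame(self) -> pd.DataFrame:
        d = {
            "cell_id": np.arange(self.depths.size),
            "ki67": self.ki67,
            "p27": self.p27,
            "rna": self.rna,
            "truth_depth": self.depths,
        }
        if self.pseudotime is not None:
            d["s"] = self.pseudotime
        return pd.DataFrame(d)


def sample_ages(n: int, prior: AgePrior, seed: int | np.random.Generator) -> np.ndarray:
    """Draw ``n`` cell ages by inverse-CDF sampling of the steady-state law."""
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    return np.asarray(prior.invcdf(rng.uniform(0.0, 1.0, size=n)))


def simulate_cell_cycle_markers(
    ages: np.ndarray,
    params: CellCycleParams = CellCycleParams(),
    seed: int | np.random.Generator = 0,
) -> CellCyclePopulation:
    """DNA and geminin-like intensities for cells of known age."""
    ages = np.asarray(ages, dtype=float)
    if np.any((ages < 0) | (ages > params.T)):
        raise ValueError("ages must lie in [0, T]")
    rng = np.random.default_rng(seed)
    n = ages.size

    # DNA: 2N in G1, linear 2N -> 4N through S, 4N in G2/M
    t0, t1 = params.t_S, params.t_S + params.s_duration
    dna_mean = np.piecewise(
        ages,
        [ages < t0, (ages >= t0) & (ages < t1), ages >= t1],
        [2.0, lambda a: 2.0 + 2.0 * (a - t0) / (t1 - t0), 4.0],
    )
    # geminin-like: logistic switch at S-phase onset to a ~(1+fold) plateau
    gem_mean = params.gem_background * (
        1.0 + params.gem_fold * _logistic((ages - params.t_S) / params.gem_rise_width)
    )
    dna = dna_mean * _lognormal_noise(rng, n, params.noise_cv)
    geminin = gem_mean * _lognormal_noise(rng, n, params.noise_cv)
    return CellCyclePopulation(
        ages=ages, dna=dna, geminin=geminin, pseudotime=None, params=params
    )


def sample_depths(
    n: int, prior: SpheroidPrior, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` cell depths by inverse-CDF sampling of the shell-volume law."""
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    return np.asarray(prior.invcdf(rng.uniform(0.0, 1.0, size=n)))


def simulate_spheroid_markers(
    depths: np.ndarray,
    params: SpheroidParams = SpheroidParams(),
    seed: int | np.random.Generator = 0,
) -> SpheroidPopulation:
    """Depth-dependent marker intensities for cells of known depth."""
    depths = np.asarray(depths, dtype=float)
    if np.any(depths < 0):
        raise ValueError("depths must be non-negative")
    rng = np.random.default_rng(seed)
    n = depths.size

    def curve(low, high, mid, width, increasing):
        z = (depths - mid) / width
        frac = _logistic(z if increasing else -z)
        return low + (high - low) * frac

    p = params
    ki67 = curve(p.ki67_low, p.ki67_high, p.ki67_mid, p.ki67_width, False)
    p27 = curve(p.p27_low, p.p27_high, p.p27_mid, p.p27_width, True)
    rna = curve(p.rna_low, p.rna_high, p.rna_mid, p.rna_width, False)
    return SpheroidPopulation(
        depths=depths,
        ki67=ki67 * _lognormal_noise(rng, n, p.noise_cv),
        p27=p27 * _lognormal_noise(rng, n, p.noise_cv),
        rna=rna * _lognormal_noise(rng, n, p.noise_cv),
        pseudotime=None,
        params=p,
    )


def _power_warp(u: np.ndarray, exponent: float = 0.6) -> np.ndarray:
    return u**exponent


def _logit_warp(u: np.ndarray, steepness: float = 3.0) -> np.ndarray:
    z = _logistic(steepness * (2.0 * u - 1.0))
    lo, hi = _logistic(-steepness), _logistic(steepness)
    return (z - lo) / (hi - lo)


#: named monotone distortions of the unit interval
DISTORTIONS = {
    "identity": lambda u: u,
    "power": _power_warp,
    "logit": _logit_warp,
    "rank_uniform": "rank_uniform",  # handled specially: uses ranks
}


def distort_to_pseudotime(
    true_values: np.ndarray,
    distortion="identity",
    seed: int | np.random.Generator | None = None,
    **kwargs,
) -> np.ndarray:
    """Monotone-warp a true scale into a synthetic pseudotime in [0, 1].

    Stands in for an external ordering algorithm: the cell *order* is
    exactly preserved (Spearman correlation 1 with the truth) while the
    pseudotime *values* are deformed by the chosen strictly increasing
    distortion.  ``rank_uniform`` maps cells to their normalized ranks,
    producing an empirically uniform pseudotime.
    """
    v = np.asarray(true_values, dtype=float)
    if v.size < 2 or np.ptp(v) == 0:
        raise ValueError("need at least 2 distinct true values")
    u = (v - v.min()) / np.ptp(v)

    if distortion == "rank_uniform" or (
        isinstance(distortion, str) and distortion == "rank_uniform"
    ):
        order = np.argsort(u, kind="stable")
        s = np.empty_like(u)
        s[order] = np.arange(u.size) / (u.size - 1)
        return s

    f = DISTORTIONS.get(distortion, distortion) if isinstance(distortion, str) else distortion
    if not callable(f):
        raise ValueError(f"unknown distortion {distortion!r}")
    s = np.asarray(f(u, **kwargs) if kwargs else f(u), dtype=float)
    # verify strict monotonicity on the realized data range
    order = np.argsort(u, kind="stable")
    du = np.diff(u[order])
    ds = np.diff(s[order])
    if np.any(ds[du > 0] <= 0):
        raise ValueError("distortion is not strictly increasing on the data range")
    rng = s.max() - s.min()
    if rng <= 0:
        raise ValueError("distortion collapsed the data range")
    return (s - s.min()) / rng


def simulate_growth_series(
    model: GrowthModel,
    days: np.ndarray,
    n_series: int = 23,
    noise_sd: float = 5.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Radius time courses from the linear growth model plus Gaussian noise.

    Returns a long-format table with columns ``series``, ``day``,
    ``radius_um`` (one row per measurement).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    days = np.asarray(days, dtype=float)
    mean = np.asarray(model.radius(days))
    rows = []
    for k in range(n_series):
        noisy = mean + rng.normal(0.0, noise_sd, size=days.size)
        rows.append(
            pd.DataFrame({"series": k, "day": days, "radius_um": noisy})
        )
    return pd.concat(rows, ignore_index=True)
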