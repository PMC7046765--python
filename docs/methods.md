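# Methods

## The transform

Let `s ∈ [0, 1]` be a pseudotime coordinate produced by any ordering
algorithm and `x` the real scale of interest (hours since division,
micrometres from a spheroid surface, or an arbitrary empirical scale).
If the cell densities `p_s` and `p_x` are positive over their supports,
their cumulative distributions are strictly increasing and the monotone
map

    τ(s) = P_x⁻¹(P_s(s))

is the unique measure-preserving transform between the two scales:
`P_x(τ(s)) = P_s(s)`, so the probability mass of any pseudotime interval
equals the mass of its image. Densities transform with the Jacobian of
the inverse map, `p_x(x) = |dτ⁻¹/dx| p_s(τ⁻¹(x))`, and joint densities
of pseudotime and a measured marker `y` transform the same way in their
first argument. Conditional profiles `p(y|x)` are obtained by
normalizing the transformed joint density columnwise, and are summarised
by quantile curves (median plus a 25–75% band by default).

The key practical property is *algorithm independence*: `P_s(s_i)` is
(asymptotically) the rank of cell `i` divided by `N`, so any two
pseudotime algorithms that order cells identically produce the same
reconstruction, regardless of how their pseudotime values are warped.

## Density estimation

Pseudotime densities are Gaussian KDEs with bandwidths from Silverman's
rule, `h = 0.9·min(sd, IQR/1.34)·N^(−1/5)`. Two boundary treatments:

* **Reflecting** (default; hard process ends, e.g. spheroid depth): each
  kernel is mirrored at `s = 0` and `s = 1`, exactly three terms per
  cell (first images only). Mass on `[0, 1]` is conserved up to far-tail
  truncation, so no renormalization is applied.
* **Linked** (cell cycle): division doubles cell numbers, so the
  steady-state density must satisfy `p(0) = 2·p(1)`. Kernel mass exiting
  the right boundary re-enters on the left with weight 2 and mass
  exiting the left re-enters on the right with weight 1/2 — equivalent
  to smoothing the extension `p(u+1) = p(u)/2`, which preserves the
  boundary ratio exactly for the steady-state age law — followed by
  renormalization to unit integral. This honours the doubling contract
  without reproducing any particular published linked-boundary
  estimator; only the boundary relation and normalization are asserted.

Joint densities are sums of product kernels (reflecting or linked in
`s`, plain Gaussian in `y`). Markers spanning several decades (e.g. a
geminin-like reporter) are estimated on log10 intensity; the flag is
carried through all downstream objects so summaries can be mapped back
to linear units.

Grids default to 512 equispaced points on `[0, 1]` for pseudotime and
256 points spanning the marker range padded by three bandwidths.

## Priors

* **Age**: `p_a(a) = 2γe^(−γa)` on `[0, T]`, `γ = ln2/T`. Closed-form
  CDF `P_a(a) = 2(1 − e^(−γa))` and inverse
  `P_a⁻¹(u) = −ln(1 − u/2)/γ`. Assumes exponential growth, no death,
  homogeneous cycle progression. Arguments outside `[0, T]` raise
  errors rather than returning 0, to surface unit mistakes early.
* **Spheroid depth**: normalized shell volume
  `P_X(x) = (r³ − (r−x)³)/(r³ − r_N³)` on the viable rim
  `[0, r − r_N]`, with density `3(r−x)²/(r³ − r_N³)` and closed-form
  inverse. The necrotic-core radius is `r_N = max(r − d_N, 0)` with
  `d_N` the depth at which necrosis begins (default 270 μm). The
  parameter 270 μm is interpreted as `d_N` — equivalently, the spheroid
  radius at which a core first appears — because a fixed core radius of
  270 μm would exceed the radius of the 11-day spheroids (~265.6 μm)
  the default growth model predicts; a fixed `r_N` remains available
  via `r_N_override` / the `r_N` config key.
* **Growth**: linear radial growth `r(t) = intercept + slope·t`
  (defaults 19.2 μm + 22.4 μm/day), fitted by pooled ordinary least
  squares.
* **Empirical**: a tabulated CDF with monotone interpolation; flat
  segments (zero-density gaps) use the left-continuous pseudo-inverse.

Units are fixed per scale — hours for age, days for growth, μm for
depth — and recorded on the prior objects.

## Numerics

`P_s` is the cumulative trapezoidal integral of the KDE, clipped to
`[0, 1]` and renormalized; `τ` is tabulated on the pseudotime grid and
interpolated monotonically. The transformed density lives on the
non-uniform grid `x_j = τ(s_j)` with the Jacobian `|ds/dx|` from central
finite differences (one-sided at the ends), which makes the interval-mass
conservation check accurate to ~1e-5 at the default resolution. Flat
stretches of `P_s` emit a warning and fall back to the left-continuous
pseudo-inverse. Conditional columns whose x-marginal is below 1% of its
maximum — profile ends where few cells sit — are masked as missing
rather than propagated as NaN.

## Trace calibration

Live-cell reporter traces `y_i(t_k)` are compared with the reconstructed
joint density by maximizing

    Σ_i Σ_k log p(t_k, (y_i(t_k) − θ₁)·θ₂)

over a global background offset θ₁ and scale θ₂ (one pair for all
cells; per-cell fitting is an option). The density is interpolated
bilinearly; values outside the grid contribute a floor density of 1e-12
before the log. The objective is maximized with Nelder-Mead on
`(θ₁, log θ₂)` — the log parametrization enforces θ₂ > 0 — from the
user's initial point, the two best points of a coarse feasibility scan
(candidate backgrounds below the trace minimum, candidate scales
aligning the trace range with the density's marker range), and wide
random restarts. The surface can hold distinct local optima when the
background is badly mis-initialized; the scan makes recovery
initialization-independent in all tested settings. The likelihood is
written without a change-of-variables term in θ₂; against a log10-scale
density θ₂ acts as a pure shift in log space, where this introduces no
bias, and in linear space the induced bias is of order CV² (≈2% at the
default noise level), well inside the tested 10% recovery tolerance.

## Synthetic data

The generators define the conditions every end-to-end test runs under.

* **Cell cycle**: ages drawn by inverse-CDF sampling from the
  steady-state law (defaults `T = 20 h`). DNA content is 2N in G1,
  linear to 4N across S (onset `t_S = 7 h`, duration 8 h), 4N in G2/M.
  The geminin-like reporter follows a logistic switch in age centred at
  `t_S` (width 0.75 h) from a background of 1 to a 100× plateau, so its
  intensity spans two decades. The smooth, symmetric switch is chosen
  so that the half-maximal rise of the (linear-scale) median identifies
  the S-phase onset itself; a reporter that kept accumulating linearly
  through S/G2 would put the half-max mid-cycle instead.
* **Spheroid**: depths drawn from the shell-volume law (default radius
  from the growth model at day 11, `d_N = 270 μm`, hence no core).
  Ki-67-like and RNA-like markers decrease, p27-like increases with
  depth, each as a logistic mean curve with stored ground-truth
  midpoints (100 / 120 / 150 μm).
* **Noise**: multiplicative lognormal with unit median, CV 0.15 —
  typical of fluorescence intensities. Unit median means the noiseless
  mean curve is also the population median curve, which is what the
  quantile summaries estimate.
* **Pseudotime**: a strictly monotone warp of the true scale, min-max
  normalized (identity, power-law, logit, or rank-uniform). This
  emulates the one property of external ordering algorithms the
  transform relies on — order preservation — and nothing else.

What the generators deliberately do not emulate: doublets, dead cells
and gating artefacts; cell-to-cell variability in cycle length;
mechanistic reporter kinetics; oxygen/nutrient gradients. Passing tests
therefore demonstrate correctness of the transform machinery under the
stated priors, not robustness to upstream data-quality problems, which
are assumed to be handled before pseudotime inference.

## Problem sizes and tolerances

End-to-end checks use 10⁴ cells — the scale at which pseudotime
algorithms are typically run on cytometry data — with 512×256 grids;
growth-model recovery uses 23 series × 15 days with 5 μm measurement
noise. Closed-form identities are tested to 1e-8, the KDE against a
brute-force kernel sum to 1e-10, interval-mass conservation to 1e-4,
and stochastic recoveries at the tolerances their sampling variability
supports (onset ±0.5 h, slope ±0.5 μm/day, calibration ±10%).

## Known limitations

* The half-max onset estimate carries a smoothing bias of order the
  kernel bandwidth expressed on the real scale (≈ +0.2–0.4 h at the
  default conditions). Strongly curved warps — e.g. a power law with
  exponent 0.6, which stretches the region near `s = 0` — can push this
  to ≈ +0.6 h, because a single global Silverman bandwidth in `s` is
  locally too wide where the warp compresses cells. Rank-uniform and
  mildly nonlinear warps keep the bias small; adaptive bandwidths are a
  possible extension and deliberately out of scope.
* The transform assumes the pseudotime ordering is correct; it can
  re-scale but never re-order cells. Orderings that locally invert
  cells propagate directly into the reconstruction.
* Zero-density pseudotime gaps make `P_s` flat and `τ` discontinuous;
  the pseudo-inverse convention keeps the pipeline defined but profiles
  across such gaps should not be interpreted.
* Only one marker channel per joint density; multivariate joint
  densities and branching trajectories are out of scope.
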