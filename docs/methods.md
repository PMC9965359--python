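# Methods

## Stress-fluctuation estimator

The relaxation modulus is estimated from the stationary autocorrelations of
the fluctuating pressure-tensor components,

    G(t) = V / (30 kB T) * sum_(ab) [ 6 C_Pab(t) + C_Nab(t) ],
    N_ab = P_aa − P_bb,   (ab) in {xy, yz, zx},

with the mean of each component removed over the full series before
correlating (not per block). In an isotropic system every shear ACF has the
same expectation C and every normal-difference ACF has expectation 4C, so
the combination equals 30 C and G(t) = V C(t) / (kB T): the six channels are
statistically independent averages of the same quantity. A constant added to
any component, or a relabeling of the Cartesian axes, leaves the estimator
unchanged. Constant (zero-variance) input is flagged degenerate rather than
raising.

Units: stresses in bar, volumes in nm³, temperatures in K, times in ps;
`kB = 0.0083144621 kJ mol⁻¹ K⁻¹` and 1 kJ mol⁻¹ nm⁻³ = 16.6054 bar.

### Multiple-tau correlator

Lags spanning ≥ 6 decades are handled by the standard hierarchical
correlator: `m = 16` points at the raw resolution, then repeated pairwise
block averaging (factor 2) with `m/2` new lags per level. Lag 0 is the exact
series variance (no averaging at level 0). Block averaging biases coarse
lags by O((block/tau)²) — second order and negligible against the
statistical error wherever the correlator resolves a decay. The test-suite
oracle is a naive loop reimplementation of the same estimator; they agree to
1e-10.

A practical point that sizing decisions rest on: the absolute sampling error
of a normalized ACF is ~ sqrt(2 tau_c / T_series) regardless of how many
molecules contribute to the summed stress — pooling molecules into one
stress signal does not shrink it. What does shrink it is averaging the ACFs
of independent subsystems. The BD simulator therefore offers `stress_groups`
(per-group virial series from one run; exact for non-interacting molecules),
and production-style estimates average independent replicas, mirroring how
replica averaging is used for long-time statistics in melt simulations.

## Viscoelastic (Rouse-type) dendrimer model

A dendrimer is coarse-grained to one bead per branch point and per terminal
group, one entropic spring per segment (`spacer_beads` refines segments into
chains). The relaxation spectrum is the graph-Laplacian spectrum under the
tethered-segment normalization — one bead on one spring to a fixed point has
eigenvalue 1 — so mode p relaxes in `tau_p = tau0 / lambda_p` and the
modulus is `G(t) = nu kB T Σ_p exp(−2 t / tau_p)` (stress is quadratic in
mode amplitudes, hence the factor 2).

Mode classification: the zero mode is translation; modes whose eigenvector
moves the core are whole-molecule (branch) relaxations; modes with zero core
amplitude split into *pulsations* (single-signed on each connected component
of their support — Perron–Frobenius ground states of subtree problems, with
times that escape above `5.8 tau0` as branches deepen) and *internal* modes
(sign-changing), which numerically always fall inside the band
`lambda ∈ [F − 2√(F−1), F + 2√(F−1)]` (checked for F = 3, G = 2–5). The
simpler classification "zero core amplitude ⇒ in band" is false — the
pulsation family sits below the band — which is why the sign criterion is
used.

G2 presets are pinned by explicit layer lists (generation-numbering
conventions differ between dendrimer literatures): PAMAM/PPI use a two-bead
core carrying four first-layer segments; PCS a single four-functional
silicon core; all yield 16 terminal groups. Compositions are assembled from
repeat-unit formulas: PAMAM `C2H4N2 + 12×C5H9N2O + 16×C5H11N2O`
(3256.2 g/mol), PPI `C4H8N2 + 12×C3H6N + 16×C3H8N` (1686.8 g/mol), PCS
`Si + 12×C4H9Si + 16×C4H9` (n-butyl terminals; 1964.35 g/mol with the
atomic-mass table used here — within 0.06 g/mol of the published 1964.3,
the difference being atomic-mass rounding conventions). The PCS terminal
chemistry is the one residual ambiguity of that preset and is validated
only against the published mass.

## Synthetic data layer

**Brownian dynamics.** Overdamped Euler–Maruyama updates
`r ← r − (K/ζ)(L r) dt + sqrt(2 kB T dt/ζ) ξ` for Gaussian phantom trees;
no excluded volume, electrostatics or intermolecular forces. Initial
coordinates are drawn from the exact Gaussian equilibrium via normal modes,
so there is no equilibration transient. Stress is the spring virial
`P_ab = −(K/V) Σ_springs b_a b_b` (fluctuating part only; the kinetic
contribution is a constant offset the estimator removes). Stability demands
`dt·K/ζ < 0.1`; discretization biases decay rates by ~`λ K dt/(2ζ)`, which
sets the timesteps used in tests. What passing BD tests shows: the
estimator chain recovers known Gaussian-chain results (equipartition,
`exp(−2t/τ)` dumbbell stress ACF with `τ = ζ/2K`, the topological-distance
closed form `⟨Rg²⟩ = (1/N²) Σ_{i<j} d_ij · 3kBT/K`, and the mode-sum
modulus). What it does not show: anything about excluded-volume, packing or
hydrogen-bond physics of real melts.

**Prescribed-spectrum stress.** Five independent latent Gaussian processes
with autocovariance `c(t) = kB T G_target(t)/V` are built as exact sums of
stationary AR(1) components (one per Maxwell mode of the Prony target) and
mapped onto the symmetric tensor so that
`<dP_ab dP_gd> = c (δδ + δδ − (2/3)δδ)` — the isotropic structure for which
the estimator's expectation is exactly the target. Power-law targets are
realized as nonnegative Prony fits (6 modes/decade over the window plus a
decade of padding; tracking error < 1 % across the window). Targets with a
mode time below `2 dt` are flagged `undersampled-mode`; negative Prony
weights are rejected as non-realizable autocovariances.

**Rotation and planting.** Rotational diffusion uses tangent-space kicks of
variance `2 D dt` per component with renormalization (`P1 = exp(−2Dt)`,
`tau_rot = 1/(2D)`; O(D dt) discretization bias). Hydrogen-bond
configurations place N–H donors and O acceptors at exactly requested
distances and donor-vertex angles, with all other beads far from any
triplet.

## Fits, spectra, superposition

* Tail fit: OLS of `ln G` vs `t`; `tau_max = −2/slope`. The default window
  selector takes the first pass of normalized G from 0.2 down to 0.01
  (scanning forward, so late-time noise cannot reopen the window). No
  automatic window detection beyond this: windows are explicit parameters,
  and the shipped configs flag them as choices.
* Log–log slopes: OLS of `log10 G` vs `log10 t` on a user window, with the
  OLS standard error.
* Master curves: each curve's time axis is multiplied by
  `tau_rot(ref)/tau_rot(i)`; curves are merged on a quasi-log grid
  (16 points/decade) by sample-count-weighted averaging, interpolating
  linearly in log-time only inside each curve's own span. Interior grid
  points covered by no curve are dropped and flagged as gaps — never
  interpolated across. Normalization uses each curve's G(0); unnormalized
  merging is available.
* Prony moduli: NNLS on log-spaced mode times (12/decade; points below
  1e-3 of the peak excluded so that irrelevant deep-tail residuals cannot
  steer the fit), then log-parametrized least-squares polishing of the
  surviving modes — NNLS alone is sparse and its fixed grid leaves a few
  per cent of placement ripple in G''. Closed forms give
  `G' = Σ g ω²τ²/(1+ω²τ²)`, `G'' = Σ g ωτ/(1+ω²τ²)`; nonnegative weights
  make both nonnegative and G' nondecreasing. The independent cross-check
  integrates the piecewise-linear interpolant of the same closed curve
  against sin/cos analytically per segment, on a grid refined to
  `Δt = 0.1/ω_max` wherever G exceeds 1e-6 of G(0) (pure log spacing leaves
  coherent chord error once `ωΔt > 1`), with linear extrapolation to t = 0
  and an analytic exponential tail beyond the data. The two routes agree to
  well under 2 % over four decades on closed curves.
* Crossover intervals: maximal runs of `G' > G''`, endpoints by linear
  interpolation of the sign change against log ω. Default ω grid:
  8 points/decade over `[0.1/t_max, 10/t_min]`.
* A curve must decay to ≤ 1 % of G(0) or carry a tail fit before a moduli
  transform; otherwise the transform refuses and names the remedy.

## Trajectory statistics

`P1(t)` is FFT-accumulated over all time origins and molecules; the default
fit window is P1 ∈ [0.05, 0.5] (configurable). The molecular axis runs from
the single selected core atom to the lowest-index periphery atom
(averaging over all periphery atoms is available behind a flag), with
minimum-image displacements. Gyration tensors are mass-weighted;
`<dRg_x²(t)>` averages squared increments of `sqrt(T_xx)` over quasi-log
lags, origins and molecules. Density profiles bin bead masses by
minimum-image distance from each reference molecule's centre of mass
(`V(r) = (4π/3)(r_out³ − r_in³)`; own-molecule vs overlap contributions
reported separately; bins past half the box are truncated with a warning).

Hydrogen bonds: donor–acceptor distance ≤ 0.35 nm and angle ≤ 30° at the
donor between the donor→H and donor→acceptor directions — for near-linear
bonds this is equivalent to the usual hydrogen–donor–acceptor criterion; the
vertex atom is configurable. Counts use the double-counting convention (a
bond contributes 2 before dividing by the number of molecules; one
ever-present intramolecular bond among 27 molecules gives 2/27 per
dendrimer). The mean lifetime is the two-sided integrated correlation time
of the intermittent (recrossing-allowed) presence indicator,
`tau = dt·Σ_{t=−∞}^{∞} C(t)` with `C(t) = <h(0)h(t)>/<h²>`: for a single
uninterrupted stretch of k frames this equals `k·dt` exactly. A
continuous-lifetime variant is out of scope; published estimates for hot
melts only bound the lifetime from above.

## Pipeline and summary

A YAML config drives generation → estimation → superposition → fits →
trajectory statistics per species; every numeric choice (windows, grids,
seeds) is echoed to `run.log`, and fixed seeds give byte-identical
summaries. The summary's derived columns — `B = tau_rot/Rg³` and
`tau_max/tau_rot` — are always recomputed from the stored primaries
(rounding: ratios 2 decimals, times and Rg 3, masses 1). With the published
PPI primaries the ratio recomputes to 0.48, not the 0.46 sometimes quoted
alongside them; the builder reports the recomputed value.

## Problem sizes and tolerances

Desk-scale runs are sized from the ACF error formula above so the
Monte-Carlo error sits well inside each check's band: e.g. the terminal-time
recovery uses four replicas of 2²² frames at dt = 50 ps (≈ 51 000 terminal
times of data; ~1.5 % statistical error against a ±5 % band) and the slope
recovery two replicas of 2²³ frames at dt = 0.5 ps (±0.005 against ±0.03).
BD checks use group-averaged stress with timesteps chosen so Euler bias
stays below half the statistical error. Statistical assertions in the test
suite are seeded and sized for ≥ 2× margin between the expected fluctuation
and the tolerance.

## Known limitations

* The bead-spring melt is an ideal (non-interacting) superposition: density
  profiles show no packing structure, and no hydrogen bonding emerges from
  dynamics — bonded configurations are planted, not simulated.
* The moduli transforms assume a completely monotone (decaying) G(t);
  oscillatory inputs are out of scope.
* `.gro` round trips quantize coordinates at 1e-3 nm (format precision).
* The PCS composition is pinned to the published molar mass; its terminal
  chemistry should be re-verified before any atomistic use.
* Temperature-based superposition is not implemented — only friction
  rescaling via tau_rot.
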