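# Methods

`mcdmri` models the pulsed-gradient spin-echo (PGSE) diffusion-MRI signal as
a mixture of biophysical compartments and recovers the mixture's parameters
voxel by voxel. This note records the models implemented, the conventions
and numerical choices behind them, what the synthetic phantoms do and do not
emulate, and the known limitations.

## Signal model

A PGSE measurement is described by the tuple (b, G, **n**, δ, Δ, TE): pulse
strength G [T/m], pulse duration δ [s], pulse separation Δ [s], unit gradient
direction **n**, echo time TE [s], and the derived quantities

    b = G² δ² γ² (Δ − δ/3)   [s/m²],     q = G δ γ / (2π)   [1/m],
    τ = Δ − δ/3              [s],

with γ = 267.513×10⁶ rad s⁻¹ T⁻¹ the proton gyromagnetic ratio. The measured
signal separates into an amplitude S₀ (TE-dependent) and a shape, the
attenuation E ∈ [0, 1]. An acquisition is grouped into shells by
single-linkage clustering of b within each unique (δ, Δ, TE) stratum, so
equal-b measurements acquired with different pulse timings are never merged;
the default linkage threshold is 50 s/mm² (separating clinically spaced
shells while absorbing vendor jitter in reported b) and shells with mean
b < 10 s/mm² are treated as b = 0. All inputs are SI; printed summaries use
s/mm², mT/m and ms.

### Compartments

Eleven compartment models generate E per measurement:

* **G1 Ball** — isotropic Gaussian, E = exp(−b λ_iso).
* **G2 Zeppelin** — axially symmetric Gaussian about **μ** with
  λ_∥ ≥ λ_⊥.
* **G3 Temporal Zeppelin** — Zeppelin whose perpendicular diffusivity
  relaxes with diffusion time, λ_⊥(τ) = λ_∞ + A·[ln(Δ/δ) + 3/2]/τ,
  modeling disordered extra-axonal hindrance. (The packing coefficient A is
  registered with the unit string m⁻² following the common tabulation;
  dimensional analysis of the formula gives m², which the default bound
  range reflects.)
* **C1 Stick / S1 Dot** — zero-radius cylinder (1-D Gaussian along **μ**)
  and non-diffusing sphere (E ≡ 1).
* **C2/S2** — cylinder/sphere under the short-gradient-pulse (SGP)
  approximation *and* the long-diffusion-time limit: the diffraction
  patterns |2J₁(x)/x|² and |3j₁(x)/x|² with x = 2πq R. These contain no
  diffusivity, hence carry no λ_intra parameter.
* **C3/S3** — finite diffusion time under SGP: the reflecting-boundary
  eigenmode series over Neumann roots of J_n′ (cylinder) and j_n′ (sphere),
  including the stationary (diffraction) mode. We derived the sphere series
  from the eigenfunction expansion and verified both series against the
  short-time limit (E → 1) and the long-time diffraction limit.
* **C4/S4** — Gaussian-phase approximation with finite pulses (the
  Neuman/van Gelderen cylinder series and the Murday–Cotts sphere form),
  valid whenever the phase accrued during δ is approximately Gaussian.

Anisotropic models factorize into parallel and perpendicular parts via
b_∥ = b(**μ**·**n**)² and q_⊥ = q·√(1 − (**μ**·**n**)²). Orientations are
(θ ∈ [0, π], φ ∈ [−π, π]) pairs, canonicalized to the upper hemisphere
(PGSE is antipodally symmetric).

Series truncation: 20 Bessel roots for the Gaussian-phase series and
12 angular orders × 12 roots for the SGP eigenmode series. Doubling either
changes the attenuation by < 1e-4 over the tested q·R range (convergence is
exercised in the test suite). The truncated eigenmode series can overshoot
1 by a few 1e-4 at very short diffusion times; values are clipped to [0, 1].

### Distributions

* **Gamma-distributed scalar** (typically the cylinder/sphere diameter):
  the attenuation is the Gamma-weighted average of the sub-model, with the
  volume weighting N(ξ) — plate ξ, cylinder πξ², sphere (4/3)πξ³ — because
  spins, not geometries, contribute signal. Quadrature: 35 trapezoid points
  spanning the central 99.7 % of the Gamma mass; this grid is a module
  constant and reproduces a 3× denser grid to ~1e-3 in attenuation on
  strong-gradient protocols. The reported mean diameter is α·β by default;
  a 2αβ convention (radius-type reading of the distributed variable) is
  available as a configuration switch, since both appear in the axon-caliber
  literature.
* **Watson dispersion** — density ∝ exp(κ(**μ**·**n**)²), parameterized by
  the orientation dispersion index ODI = (2/π)·arctan(1/κ) (0 = spike,
  1 = uniform). The normalization constant 4π·M(½, 3/2, κ) is evaluated
  exactly with the confluent hypergeometric function; the z-aligned m = 0
  spherical-harmonic coefficients come from 128-node Gauss–Legendre
  quadrature and are carried to arbitrary orientations by the addition
  theorem, avoiding any spherical-harmonic rotation machinery.
* **Bingham dispersion** — density ∝ exp(κ₁(**μ**·**n**)² + κ₂(**μ₂**·**n**)²)
  with κ₁ from ODI as in the Watson, κ₂ = β·κ₁ (β ∈ [0, 1] guarantees
  κ₂ ≤ κ₁), and a roll angle ψ orienting the secondary axis about **μ**.
  The normalizing constant is integrated numerically on a 128×256 product
  Gauss grid (exact in azimuth for the cos²φ integrand; spectral in the
  polar variable), accurate to ~1e-12 over the exposed ODI range. At β = 0
  the density equals the Watson to ~1e-14.

Dispersed composites evaluate as per-shell spherical convolutions in the
real, antipodally symmetric (even-degree) spherical-harmonic basis: the
kernel mixture's rotational harmonics r_{s,l} (Gauss–Legendre in cos θ)
are combined with the distribution's coefficients degree-wise through the
Funk–Hecke factor √(4π/(2l+1)). The dispersion order defaults to l ≤ 14;
the residual truncation error only matters for near-spike dispersions
(ODI ≲ 0.05), where it decays with increasing order.

### Tissue responses

Measured (non-parametric) responses average the per-voxel rotational
harmonics of the raw signal across segmented voxels and carry the mean b0
intensity S₀ separately. Anisotropic responses first rotate each voxel's
gradient directions so the principal eigenvector of a log-linear tensor fit
points along z; degenerate tensors are skipped with a logged count. Tensor
fits are restricted to b ≤ 1500 s/mm² — above that, low-diffusivity
assumptions fail and noise-floor effects bias CSF statistics. Per-shell
m = 0 coefficients are fitted by least squares on the rotated directions,
with the fitted degree capped by the shell's direction count and b0 shells
represented by their mean alone. The three-tissue voxel selector is a
documented heuristic (high FA → white matter; fast decay and bright b0 →
CSF; low FA with moderate diffusivity → gray matter), validated on
phantoms only; it does not reproduce any specific published segmentation
algorithm.

## Multi-compartment flavors

A `MultiCompartmentModel` aggregates sub-models under prefixed parameter
names with volume fractions, in one of three flavors:

* **MC** — E(A) = Σᵢ fᵢ Cᵢ(A; pᵢ) per measurement;
* **MC-SM** — per-shell spherical means. Dispersion and crossings leave the
  spherical mean invariant (the distribution integrates to 1), so
  orientation parameters are removed. Measured spherical means are
  arithmetic per-shell direction averages, adequate for the near-uniform
  direction sets used here.
* **MC-SH** — the anisotropic kernel is convolved with a non-parametric
  even-order SH fiber orientation distribution (FOD); isotropic
  compartments contribute scalar fractions. Only one anisotropic kernel may
  carry a free fraction; several can be mixed into one effective kernel if
  their relative fractions are fixed.

Parameters can be fixed (globally, or voxel-wise for cascading a previous
fit), linked equal, or tied by the tortuosity rule
λ_⊥ = (1 − f_intra)·λ_∥. Tortuosity lives at the distributed-model level;
at the plain MC level it is rejected because it would make a volume
fraction non-linear, breaking the contract that linear-in-fraction
optimizers rely on. The spherical-mean flavor accepts MC-level tortuosity
(its fitting goes through the general non-linear optimizer), which is what
the per-axon spherical-mean preset requires. With per-model S₀ amplitudes
set, predictions are signal-scale rather than attenuation-scale, enabling
multi-tissue fitting.

## Optimization

* **brute2fine** (MC/MC-SM): every free scalar is sampled on an equispaced
  grid of Ns = 5 points within its bounds, orientations on a 30-point
  hemisphere set, and fraction simplices through the nested transform
  f₁ = x₁, f₂ = (1−x₁)x₂, …; the best grid point seeds a bounded L-BFGS-B
  refinement (unit-box rescaled coordinates, numerical gradients, ftol
  1e-14, ≤ 300 iterations). Grids beyond 50 000 candidates are subsampled
  with a warning. Parameter combinations violating a model's physical
  constraints (e.g. λ_⊥ > λ_∥) are assigned infinite misfit rather than
  raising.
* **MIX** (MC/MC-SM): differential evolution (rand/1/bin, population 15×,
  CR 0.7, dithered F ∈ [0.5, 1], seeded) over the non-linear parameters
  with volume fractions solved by non-negative least squares at every
  candidate, followed by a joint local refinement. Models whose links make
  fractions non-linear are rejected with a pointer to brute2fine.
* **Tournier-style CSD** (MC-SH): iteratively reweighted Tikhonov scheme —
  penalty rows at grid directions where the current FOD falls below 10 % of
  its mean, with a scale-free regularization weight; negative lobes are
  discouraged, not forbidden. Requires fixed fractions for any additional
  kernels.
* **Constrained CSD** (MC-SH): the quadratic program
  min ‖data − prediction‖² s.t. FOD ≥ 0 on a 362-point hemisphere grid and
  isotropic fractions ≥ 0, optionally with the unity constraint
  Σ fractions = 1 (default on, but off when S₀ responses are given, where
  it is counterproductive). Solved by an in-package ADMM splitting with
  residual-balanced penalty adaptation, a strict-feasibility projection
  (raising c₀₀ lifts the FOD uniformly at negligible objective cost), and
  an active-set KKT polish that snaps exactly-representable solutions to
  machine precision. This solver was chosen after a general-purpose SLSQP
  approach proved silently unreliable on the rank-deficient single-shell
  problems below.
* **Multi-tissue fraction correction**: after the non-linear parameters are
  fixed, volume fractions are re-estimated against the *raw signal* by
  voxel-wise non-negative least squares on S₀-weighted compartment
  predictions, then normalized. Attenuation-only fitting implicitly assumes
  equal S₀ per tissue and is provably biased otherwise (a 2:1 S₀ ratio at
  true fractions ½/½ yields a ⅔/⅓ attenuation fit; the corrected fit is
  exact).
* **SS3T** (single-shell three-tissue): with two isotropic responses, one
  anisotropic response, S₀ amplitudes, and data containing exactly one
  diffusion-weighted shell plus b0, the schedule alternates partial convex
  fits — initialize with the white-matter FOD at zero and fit the two
  isotropic fractions; then, holding CSF, fit the FOD and the gray-matter
  fraction under the non-negativity constraints; then, holding the FOD,
  re-fit both isotropic fractions — for a fixed number of iterations
  (default 4). The early stop is essential: the single-shell problem is
  degenerate (a one-parameter family of exact fits trades FOD mass against
  the isotropic fractions), and the fixed iteration count keeps the
  estimate near the low-white-matter initialization path, which passes
  close to the multi-shell solution.

All optimizers fit voxels independently and are deterministic under a fixed
seed. Results objects carry per-voxel parameter maps, mean squared
residual, R², non-convergence flags, FOD evaluation/peak extraction (grid
maxima refined by local optimization on the sphere), and a `summary()`
table.

## Synthetic phantoms: what they show and what they do not

The phantom module generates the acquisition regimes in which each preset
is used: a low-b (≤ 1000 s/mm², 21-measurement) protocol for the
two-Gaussian perfusion model; a multi-(δ, Δ) strong-gradient protocol
(δ = 3/8/8/8 ms, Δ = 7/12/25/40 ms, G ≤ 0.849 T/m) for Gamma-diameter
cylinders; a three-shell protocol (b = 1000/2000/3000 s/mm², δ/Δ =
10.6/43.1 ms) for crossing, dispersed and three-tissue voxels. Ground-truth
parameter draws are fixed, documented ranges chosen to be tissue-realistic
(e.g. perfusion fractions 0.05–0.35, axon mean diameters 1.5–5 μm,
bundle ODI 0.15–0.6 for dispersed voxels). The three-tissue phantom gives
CSF a 3× brighter S₀ than white/gray matter, and its mixed voxels model
white matter as coherent single bundles (ODI ~ U(0.03, 0.10), the range
reported for coherent tracts) — the regime in which single-shell
three-tissue fitting is used in practice. Noise is Gaussian or Rician
(magnitude of a complex Gaussian; SNR defined at the b0 amplitude), seeded
and reproducible.

Passing phantom tests therefore demonstrates the *self-consistency* of the
forward models and optimizers — simulate-and-refit identifiability, the
analytic invariances, and the solver contracts — under ideal conditions:
no partial-volume grids, no motion/eddy artifacts, no spatially correlated
noise, no susceptibility distortion, and generating models drawn from the
package's own families. They say nothing about whether a given compartment
mixture is the *right* biological description of real tissue.

A specific case is the single-shell three-tissue comparison: on a noiseless
phantom exactly representable by the responses, every exact fit is a fixed
point of the alternating schedule, so the schedule simply parks where the
initialization lands and no shell-dependence can appear. The head-to-head
with multi-shell fitting is therefore run at a realistic SNR (Rician, 50),
where the near-collinearity of the gray-matter and white-matter responses
at b = 1000 s/mm² amplifies noise exactly as observed on real data, and
agreement with the multi-shell fit improves at b = 3000 s/mm².

## Preset defaults

Literature-standard fixes applied by the presets: white-matter parallel
diffusivity 1.7×10⁻⁹ m²/s (shared across Stick and Zeppelin, and fixed for
the diameter-distribution preset); free-water diffusivity 3×10⁻⁹ m²/s;
perfusion ("blood") diffusivity bounds 6–20×10⁻⁹ m²/s with the tissue
compartment at 0.5–6×10⁻⁹ m²/s, and a 7×10⁻⁹ m²/s fixed-blood variant. The
sphere/stick diffusivity defaults in the `verdict` and `activeax`
compositions are package configuration values, not literature claims. The
spherical-mean NODDI-style composition fixes its (spherical-mean-invisible)
dispersion index, since the spherical mean carries no information about it.

## Known limitations

* PGSE only: no double-diffusion encoding, free waveforms, or exchange.
* Axially symmetric kernels only; a Bingham-dispersed composite has no
  rotational-harmonics representation and cannot serve as a convolution
  kernel.
* The three-tissue voxel selector is a phantom-validated heuristic, not a
  validated segmentation method for clinical data.
* Voxels are fitted serially; there is no multi-core dispatch. Problem
  sizes in the test and acceptance workloads (2–200 voxels per study) were
  chosen to exercise every pipeline at desk scale.
* Measured tissue responses are defined on the shells of their estimation
  scheme; using them on a scheme with different timings or unmatched
  b-values raises an error rather than extrapolating.
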