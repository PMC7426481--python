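# Methods

## Problem and model

The medium is a 1D layered slab: `n_layers` uniform layers of thickness `dz`
(cm), laterally infinite and homogeneous, with known per-layer scattering
coefficient μs (cm⁻¹), Henyey–Greenstein anisotropy g and (matched)
refractive index.  The unknown is the per-layer absorption coefficient μa
(cm⁻¹).  Light propagation obeys the radiative transfer equation, solved
stochastically by photon-packet Monte Carlo; the tallied quantity is the
fluence Φ (angular integral of the radiance), layer-averaged.

Data models:

* QPAT: h = μa·Φ with Φ from a collimated, normally incident unit-power
  source at z=0.
* UMOT (transmission): b = η·Φq·Φm, with Φq from the source at z=0 and Φm
  from a collimated virtual source at z=d reciprocal to the detector; η is a
  per-layer ultrasound-focus weight, 1 everywhere by default (ideal delta
  focus scanned over every depth).

Both costs are discrete L2 with dz quadrature, F = ½Σ(obs−model)²·dz, so
values approximate the depth integral and transfer across grid resolutions;
the truth-referenced error F_μa = ½Σ(μa_true−μa)²·dz uses the same
convention.

Gradients with respect to μa come from adjoint transport under the
isotropic-radiance (fluence) approximation ∫φ*φ dŝ → Φ*Φ:

* QPAT: ∇F = −Φ(h_obs−h) + Φ*Φ, adjoint source Q_adj = μa(h_obs−h).
* UMOT: ∇F = Φ*¹Φm + Φ*²Φq, adjoint sources Q¹ = ηΦq(b_obs−b),
  Q² = ηΦm(b_obs−b).

These gradients are per-depth densities; the partial derivative of F with
respect to one layer's μa equals the density times dz (the finite-difference
validator converts accordingly).  The fluence approximation is exact only for
isotropic radiance; it is poorest near collimated sources and at high g, and
contributes a small systematic component to the measured ~1% gradient
discrepancy.

## Transport engine

A single numba kernel propagates packets for every source type.  Design
choices:

* Scattering free paths are sampled from μs alone; absorption is applied as
  continuous weight attenuation exp(−μa·ℓ) along each track segment.  The
  fluence tally is the track-length estimator with analytically integrated
  segment weight (w_in − w_out)/(μa·dz), falling back to w·ℓ/dz as μa → 0,
  so the estimate is well-defined at zero absorption (the iterate may visit
  it).  Both choices lower variance relative to the discrete-interaction
  (MCML albedo-weighting) scheme while leaving expectations unchanged.
  A corollary used throughout validation: trajectories depend only on
  (μs, g), so runs sharing a seed share trajectories across different μa,
  enabling common-random-number finite differences.
* Only the z direction cosine is tracked (lateral symmetry); the
  Henyey–Greenstein deflection cosine uses the standard inverse CDF, the
  azimuth enters through cos φ.
* Roulette below weight 10⁻⁴ with survival probability 0.1 (conventional
  values; configurable).  Expected reflected + transmitted + absorbed weight
  is exactly 1 per launched packet.
* Refractive indices are matched (no Fresnel/specular reflection); index
  mismatch is out of scope.
* Signed (adjoint) sources are simulated as two non-negative parts with the
  photon budget split proportionally to integrated source power (≥1 packet
  per nonzero part) and the power-scaled results subtracted.
* RNG is an explicit xorshift128+ stream seeded via splitmix64, so a
  (inputs, seed) pair reproduces a fluence profile bit-for-bit.  All
  sub-seeds derive from one master seed through `numpy.random.SeedSequence`.
* Per-photon tally second moments are accumulated, giving per-layer standard
  errors used by the test suite's 3-standard-error checks.

A degenerate guard: a packet travelling exactly parallel to the layers in a
non-scattering layer can never leave; its remaining weight is deposited (or
discarded when μa = 0).  This is a measure-zero event for all supported
sources.

## Oracles

One QPAT oracle call with |S| packets spends ⌊|S|/2⌋ on the forward run and
the remainder on the adjoint; UMOT quarters the budget (remainder to the
first adjoint run).  The sampled cost uses the call's own forward fluence and
is therefore itself noisy.  Photon accounting is exact.

The sampled gradient reuses the forward fluence sample inside the residual
term (and inside the adjoint source), which introduces an O(1/|S|)
correlation bias: E[Φ·μaΦ] = μa(Φ̄² + Var Φ) ≠ μa Φ̄².  Measured at a stalled
iterate on the 80-layer slab this is ~20% of the gradient norm at |S|=200 and
~5% at |S|=2000; it vanishes as the sample grows and is shared by the
standard forward–adjoint formulation this package implements.  The
finite-difference validation and the unbiasedness test therefore run at
sample sizes (≥10⁵ and 2000 respectively) where the effect is below Monte
Carlo resolution.

## Controller

`run_inversion` performs x ← x − α∇F_Sn with projection onto μa ≥ 0
(optional, off for the abstract test oracle), under a total photon budget;
the loop terminates when the next iteration would exceed the budget (never
truncating an iteration).  Metrics are evaluated at iterations 1, 1+T, 1+2T…
from N_rep fresh oracle calls at the current sample size; the iteration-1
evaluation supplies the first step size for strategies 2–3.  Updates always
use a fresh gradient sample, never the metric mean.  Metric photons are
excluded from the budget by default (configurable).  Sample sizes are rounded
up to the oracle's granularity (2 for QPAT, 4 for UMOT); κ is clamped to ≥1.
Discrepancy-principle early stopping on the sampled cost is available and off
by default.

Variance metrics use the N_rep sample mean ḡ as the stand-in for ∇F with the
n_rep−1 divisor:

    V²_tot = Σ‖g_j−ḡ‖²/(N_rep−1)/‖ḡ‖²,
    V²_par = Σ⟨g_j−ḡ, ḡ⟩²/(N_rep−1)/‖ḡ‖⁴.

V²_par ≤ V²_tot always (Cauchy–Schwarz), and both scale as 1/|S|.

### Metric saturation — practical guidance on choosing γ

Because ḡ carries its own noise, E‖ḡ‖² = ‖∇F‖² + E‖ε‖²/N_rep, the plug-in
metrics saturate once noise dominates: V²_tot ≲ N_rep and, for noise of
effective dimension d_eff, V²_par ≲ N_rep/d_eff, with outlier-driven spikes
bounded near √N_rep.  The consequence is that thresholds γ above the
saturation ceiling can never fail, the sample size never grows, and the
descent settles at the fixed-sample noise floor.  Where that ceiling sits
depends on the estimator's noise geometry: with this package's low-variance
continuous-attenuation estimator the QPAT gradient noise has d_eff ≈ 16 on
the 80-layer slab, capping V_par below ~1 even at N_rep=100, whereas the
UMOT problem's lower-dimensional noise lets V_par reach ~8–11.  Heavier-
tailed estimators (e.g. discrete-interaction weighting at very small photon
counts) operate near the √N_rep outlier ceiling, which is the regime in
which γ_par values of order 10–20 are meaningful.  Rule of thumb for this
package: pick γ safely below the observed early-descent metric scale (QPAT:
γ_par ≈ 0.3–1; UMOT: γ_par ≈ 5–15), or use the norm test, whose ceiling
√N_rep is higher.  γ is always explicit configuration; no value is
hard-coded.

Fixed-sample control experiment (80-layer QPAT slab, strategy-1 step
α=0.2, budget 2×10⁶): |S|=200 stalls at ~13% of the initial F_μa, |S|=2000
reaches 0.6%, |S|=20000 exhausts the budget before converging — the classic
noise-floor/budget trade-off the adaptive controller is designed to
navigate.

## Synthetic data and scope

"Observed" data are generated by running the forward model at the true μa
with a large photon count (10⁷ by default in the examples; the sampling
noise of the observed vector then sits well below every other noise source,
emulating an effectively deterministic measurement).  The phantom generator
produces piecewise-constant profiles: a background (default 0.1 cm⁻¹) plus
rectangular bumps; the worked examples use bumps of +0.4, +0.15 and +0.25
cm⁻¹ centred at 0.35, 1.0 and 1.6 cm — background-to-peak contrast of the
character used in layered-phantom studies.  Not emulated: measurement noise
beyond Monte Carlo sampling, the acoustic stage of QPAT (h_obs is taken as
given), the Grüneisen factor, scattering-coefficient gradients, index
mismatch, 2D/3D heterogeneity.  Passing tests therefore demonstrate the
estimator/controller machinery on idealized noise-free-data conditions, not
robustness to experimental noise.

## Problem sizes in the test suite

The default suite sizes simulations for a single CPU: transport limits at
10⁵ packets, sampler moments at 10⁶ draws, gradient validation with a
10⁷-packet mean oracle gradient against finite differences at 10⁶ packets
per evaluation, and one full 80-layer QPAT inversion with the 2×10⁶-photon
budget and observed data from 10⁷ packets.  The acceptance script adds a
UMOT inversion at a 4×10⁶-photon budget (a 100× scale-down of the full
4×10⁸ regime, with |S1|=4000 and L=50 retained).

## Known limitations

* The fluence approximation biases gradients near collimated sources at high
  g (measured ≈1% aggregate on the validation slab).
* The plug-in variance metrics saturate as described above; thresholds must
  be chosen for the estimator at hand.
* The small-|S| oracle correlation bias shifts the stall point of very
  low-sample descents.
* Layered (1D) geometry only; properties and estimate share one uniform
  grid.
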