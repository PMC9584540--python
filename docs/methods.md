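# Methods

## Model and assumptions

The network is a 1D ring with two populations L and R of N neurons each.
Synaptic inputs g evolve by leaky integration of recurrent input, a resting
input A, a drive term ±γb, and noise; rates are s = φ[g]. The connectivity
is a translation-invariant inhibitory cosine kernel of depth w, strongest
at the inhibition distance l and zero beyond 2l, with the synaptic outputs
of populations L/R rotated by ∓ξ lattice sites. ξ is restricted to integer
values because the network lives on a lattice; non-integer shifts are
rejected rather than interpolated. When the kernel support extends past the
ring (single-bump networks), the tails are wrapped around rather than
truncated, which preserves the total inhibition per neuron exactly.

Assumptions inherited from the model class: rates are non-negative and
instantaneous functions of g; the drive b is constant within a run; the
three noise sources are studied one at a time; bump motion is rigid enough
that a single scalar position per bump describes the state (the tracker
checks this only through its ambiguity guards).

## Parameters

| parameter | meaning | default (rate / spiking) |
|---|---|---|
| τ | neural time constant | 10 ms |
| Δt | Euler timestep | 0.5 ms / 0.1 ms |
| A | resting input | 1 / 0.1 ms⁻¹ |
| γ | drive coupling | 0.1 / 0.01 ms⁻¹ |
| ξ | connectivity shift | 2 neurons |
| l | inhibition distance | 0.44 N/M |
| w | kernel depth | 8 M/N |
| burn-in | formation steps before data | 1000 |

l = 0.44 N/M inverts the wavelength-selection result λ = 2.28 l so that the
preferred wavelength equals the bump spacing N/M; w = 8M/N keeps the summed
kernel weight per neuron, and hence the bump shape in units of x/λ,
invariant across (M, N). Under the circular coordinate mapping γ is
rescaled by (N/600)(3/M), anchored at the (N, M) = (600, 3) configuration,
so a given drive produces the same angular velocity for every architecture.

Noise parameters: input noise draws ζ ~ N(0, σ²) independently per neuron
and timestep (σ = 0.5 in the standard experiments). The stated covariance
σ²Δt δ(t−t′) fixes the discretization: with δ(t−t′) → 1/Δt on the grid the
per-step variance is exactly σ², which is what makes the predicted
D_input carry its σ²Δt prefactor. Spiking noise replaces the deterministic
rate in the recurrent input by s = c/Δt with c = F·Poisson(φ[g]Δt/F), so
counts are multiples of the Fano factor F with mean φ[g]Δt and variance
F φ[g]Δt; the drive and resting terms stay deterministic. Connectivity
noise adds a quenched dense 2N×2N Gaussian matrix V (per-entry SD
"magnitude", 0.002 in the standard experiments, applied to all four
population blocks, no N-dependent rescaling, ξ ignored inside V) whose
contribution enters the dynamics as ζ = V s.

## Simulation engine

Explicit Euler updates on batched states (B, 2, N), with the recurrent
term computed by FFT circular convolution and the population shifts applied
as spectral phase factors (verified against dense-matrix multiplication in
the tests). Batches integrate replicate ensembles in lockstep; all
randomness for a batch is drawn from one seeded generator, so every
ensemble is bitwise reproducible given (seed, configuration, batch layout).
The quenched-noise product V s is evaluated in single precision: V is a
~10⁻³ perturbation, and this product dominates the step cost of
connectivity-noise runs.

Bump formation starts from g = A(1 + 0.01·N(0,1)) i.i.d. — jitter small
enough not to bias mode selection but sufficient to break translation
symmetry — and runs the burn-in with b = 0. Seeded formation (used by the
information protocol and the trapping experiments) adds a Gaussian bump of
amplitude A and width λ/8 at each requested phase, held for the first half
of the burn-in and ramped linearly to zero over the second half. Any
sufficiently localized, slowly removed input would do; amplitude, width,
and ramp here are package choices, validated by the requirement that the
formed bump sit within ~1 neuron of the request.

Baseline profiles for the theory are taken from noiseless, driveless
simulations (formation plus a relaxation of 4000 extra steps, or until the
per-100-step change falls below 10⁻¹²), not from the closed-form shape.
The slowest lattice mode decays with a ~2 s time constant, so residuals
after the default relaxation are ~10⁻⁶ and irrelevant to the integrals;
tests that need the fixed point to machine precision relax longer.

## Theory evaluation

The closed-form kernel spectrum W̃(q) = −wk² sin(2πq/k)/(k²q − q³), k=π/l,
has removable singularities at q = 0 (value −2πw/k) and q = ±k (value
πw/k), patched explicitly. The preferred wavenumber is found by a 4096-
point grid scan bracketing a bounded scalar minimization (tolerance
10⁻¹²); a brute-force grid at 10⁻⁵ resolution confirms the maximizer in
the tests. The bump-shape parameter ψ = κz solves
ψ − cosψ sinψ = π/(2W̃(κ)) by Brent root-finding on [10⁻⁶, π−10⁻⁶]
(tolerance 10⁻¹⁰). The single-harmonic profile that follows is an
approximation: against simulated baselines it tracks the firing region to
within ~6% of max|g| but overshoots the inhibited troughs by up to ~20%,
so it is used for validation and for Lyapunov orderings, never as the
input to the dynamical predictions.

The dynamical formulas (v_drive, D_input, D_spike, v_conn, b₀, speed
statistics) reduce to integrals of φ′-weighted derivatives of the baseline
g. These are evaluated on the trigonometric interpolant of the lattice
profile, upsampled 16×, with spectral derivatives: g is smooth, and naive
central differences plus a whole-site mask at the bump edge introduce an
O(1/bump-width) quadrature error (several percent at λ ≲ 100 neurons) that
the subcell evaluation removes. The kink sites are thereby handled by
resolution rather than by an ad hoc exclusion rule. The drift field
v_conn(θ) is the one genuine per-neuron double sum (V is defined on the
lattice); it uses spectral derivatives sampled at lattice sites, with the
baseline profile first recentred so a bump sits at position 0 — the
translation s(j−θ) in the formula presumes that alignment. Velocities are
converted to neurons/s (ms → s factor 1000), and under circular mapping to
degrees/s with the 360M/N factor (squared for diffusion coefficients).

The Lyapunov functional uses the ξ-symmetrized single-population kernel
(W(d−ξ)+W(d+ξ))/2, which is the interaction that actually governs the
driveless two-population dynamics; at ξ = 2 ≪ l the difference from W is
cosmetic, but the symmetrized form is what makes the non-increase property
hold exactly. The reduced steady-state form −(A/2)Σs agrees with the full
functional to ~10⁻⁸ relative at fixed points.

## Tracking and estimators

Bump positions come from the summed rates: a circular center of mass with
periodicity N/M gives a global phase; the ring is partitioned into M
near-equal segments, rotated so the phase sits mid-segment (integer
rounding as stated), and per-segment centers of mass are taken. Bump
existence uses a relative threshold of 10⁻⁶·max(S) — scale-free, and
checked against brute-force thresholding over a range of cuts. Identity
labels follow nearest-ring-distance matching frame to frame (cyclic-order
preserving for the offline path, per-bump arg-min for the batched online
path); matching refuses frames with two bumps within one neuron.

Velocity: mean displacement Θ(u) over offsets u = Δt … T/2, fitted through
the origin (slope = Σuy/Σu², exact least squares). Diffusion: per-bump
deviations from the ensemble mean, squared-displacement curves Ω(u)
computed via cumulative sums and an FFT autocorrelation, ensemble-averaged
and fitted to 2Du; ensemble averages pair one bump per simulation by
identity. Bootstrap uncertainties resample replicates with replacement (48
resamples of 48 by default) and rerun the full estimate. On synthetic
Brownian ensembles the estimator shows only the expected −1/R bias from
ensemble-mean subtraction (~2% at R = 48) with ~12% single-experiment
scatter; the oracle tests therefore average several experiments before
asserting the 10% bias bound.

Escape drive: 8 rounds of bisection on (0, 1.28] for each drive sign
(accuracy 0.01), classifying each test run as traversing (every integer
position visited by a bump) or trapped. The trapping criterion is a
package choice: all
bumps displace less than 0.25 neurons over a trailing 500 ms window
(equivalently, speed < 0.5 neurons/s sustained), far below driven speeds
at the search floor. Runs are capped at 60 s simulated time (40 s in the
test suite); a cap without traversal counts as trapped, which can
overstate b₀ by at most the bisection step near the threshold. Speed
profiles record positions every 2 ms (inter-sample motion ≪ 1 neuron),
smooth instantaneous velocities with a Gaussian kernel of σ = 10 ms
(reading "width" as the standard deviation, truncated at ±3σ), and bin by
integer position.

## Coordinate mappings and mutual information

Linear mapping: 1 cm per neuron, the choice that makes the 200 cm wide
coordinate range coincide with the bump distance of the (600, 3) reference
network, so the onset of bump ambiguity falls exactly at the wide-range
boundary. Circular mapping:
360·M/N degrees per neuron, capped at a 360° range.

The information protocol initializes replicates at 20 evenly spaced
coordinates (seeded formation at the mapped phases), evolves them 5 s
under input noise with no drive, and records final rates of all 2N
neurons. Rates are binned into 6 equal bins from 0 to the 99th percentile
pooled across all neurons and samples of one experiment (overflow into the
top bin; all-equal degenerate edges put everything in the lowest bin).
Mutual information uses base-2 logs, uniform p(u), 0·log0 = 0, and p(s) by
marginalization; the implementation is pinned to a brute-force double sum
at 10⁻¹² tolerance. Cues are quadrant labels of the coordinate range,
giving a 6×4 joint state space; cues alone carry exactly 2 bits.
Replicates whose final bump count differs from M are excluded and logged.
Standard errors of mean MI are bootstrapped over neurons.

## Problem sizes in the test suite

The suite runs the full protocols at the sizes that make their claims
measurable on one core: 48-replicate ensembles for diffusion (5 s runs),
one quenched-noise realization for the escape-drive comparison and three
for the speed statistics, 48-realization theory ensembles for the
connectivity-noise scaling laws, and 10-coordinate × 16-replicate
information experiments at N = 300 for the trend checks (the full 20 × 96
protocol is available through the CLI). The information trends are
therefore tested as orderings with bootstrap errors, not as absolute
values.

## Known limitations

- The single-harmonic closed-form bump shape is ~20% off in the inhibited
  troughs; all quantitative predictions use simulated baselines instead.
- The ∝ N/M² and ∝ N/M scaling laws are continuum statements; lattice
  fixed points deviate by a few percent at bump spacings λ ≲ 100 neurons
  and more strongly below λ ≈ 50, so the scaling suite scans M at N = 600
  and N at M = 3, where spacings stay ≥ 66 neurons.
- Mixed noise sources, plastic or excitatory connectivity, sub-lattice
  position interpolation, 2D (toroidal) generalizations, and multi-neuron
  joint information are out of scope.
- Logistic-activation parameters are exposed (gain 2, threshold 1,
  saturation 3 — chosen so a noiseless one-bump state exists) but the
  package's quantitative results are for ReLU.
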