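# Methods

## Model

The tissue is described by the bidomain equations for the transmembrane
potential v (mV) and extracellular potential u_e (mV):

    ∇·(M_i ∇v) + ∇·(M_i ∇u_e)         = χ C_m ∂v/∂t + χ I_ion,
    ∇·(M_i ∇v) + ∇·((M_i + M_e) ∇u_e) = 0,

with zero-flux (Neumann) conditions on both the intracellular and
extracellular currents. Lengths are kept in cm, time in ms, conductivities
in mS/cm, capacitance in µF/cm² and potentials in mV, so both sides of the
equations are in µA/cm³ without conversion factors. Under pure Neumann
conditions u_e is defined only up to an additive constant; the gauge is
fixed by the mass-weighted zero-mean constraint ∫u_e = 0, enforced with a
Lagrange multiplier so the linear system stays square and nonsingular on
any mesh.

The ionic current I_ion is the Cressman conductance-based neuron: sodium
(instantaneous activation m_∞(v), inactivation h), potassium (activation
n, plus a small calcium-gated afterhyperpolarisation current), chloride
leak, and slow equations for extracellular potassium K_o and intracellular
sodium Na_i driven by the membrane fluxes, a Na/K pump, glial uptake and
lateral diffusion of K⁺ toward a bath value k_o,∞. Reversal potentials are
Nernst expressions in the instantaneous concentrations; the intracellular
potassium and extracellular sodium pools are closed by conservation
relations. The full state per neuron is (v, n, h, K_o, Na_i, Ca_i); the
calcium variable is retained because removing the afterhyperpolarisation
current measurably changes burst statistics.

The single regime-setting parameter is the bath potassium k_o,∞: 4 mM
gives a stable resting neuron, 8 mM a seizure-like burster. All remaining
coefficients (conductances g_Na = 100, g_K = 40, leaks 0.0175/0.05/0.05
mS/cm², pump rate ρ = 1.25 mM/s, glial uptake 200/3 mM/s, K diffusion rate
4/3 s⁻¹, volume ratio β = 7, current-to-concentration factor γ = 0.0445
mM·cm²/µC, gating rate φ = 3, RT/F = 26.64 mV) are the published values of
the source neuron model, with the corrected ("thirds") uptake/diffusion
rates where the literature prints both variants. The transcription is
pinned by a second, independent re-implementation of the right-hand side
compared term-by-term at random states in the test suite, and by the
regime behaviours the model is known for: five spikes then silence at
4 mM, a multi-second burst of >200 spikes at 8 mM.

## Initialization

No initial condition is canonical for this model, so the package fixes a
documented seed state, (v, n, h, K_o, Na_i, Ca_i) =
(−50 mV, 0.08553, 0.96859, 7.8 mM, 15.5 mM, 0), the source model's own
starting point. Every neuron — stable or unstable, point model or tissue
node — starts there by default; regimes differ only through k_o,∞. This
has two consequences that are part of the modelled protocol: the stable
model fires a small transient of ~5 spikes while relaxing, and stable
tissue is transiently sensitized (elevated K_o) during the first seconds,
which is what lets waves from the unstable focus keep re-igniting the
surrounding grey matter. `cressman_rest_state` instead relaxes the model
with an adaptive integrator (LSODA, rtol 1e-10) and polishes the endpoint
with a root solve; for stable parameters it returns a genuine fixed point
(scaled derivative norm < 1e-8, flagged `stationary`), for unstable ones a
reproducible phase reference flagged non-stationary. It is available for
experiments that require a settled start.

## Geometry and meshing

The idealized head slice is a 60 mm × 40 mm rectangle layered from the
top: scalp, skull, CSF, grey matter (4 mm each), white matter (the
remaining 24 mm). A central band of grey matter, 4 mm wide (configurable),
carries the unstable regime. The white matter splits at the vertical
midline: vertical fibre orientation on the left, horizontal on the right,
with transversely isotropic tensors σ_l = 1, σ_t = 0.1 mS/cm applied to
both M_i and M_e (configurable to either field alone). Conductivities
elsewhere (mS/cm, intracellular/extracellular): GM 1/2.78, WM 1/1.26,
CSF 10⁻⁴/17, skull 10⁻⁴/0.1, scalp 10⁻⁴/4.3 — passive tissue keeps a
nominal 10⁻⁴ intracellular conductivity so v remains defined everywhere
while carrying no cell model.

The mesh generator produces a structured, conforming triangulation with
one knob that matters scientifically: the number of element rows across
the grey matter. The membrane space constant of the stable tissue is
~0.6 mm, and sustained wave propagation requires the GM to be resolved
near that scale in both directions; the default (5 rows across the 4 mm
GM, matching horizontal spacing, ~3450 cells) is the coarsest
configuration that propagates every wave. Under-resolved meshes (2–3 rows,
~600–1200 cells) lose propagation after the first few waves — a physical
discretization effect this package reproduces deliberately, and which is
stable under uniform refinement of the default mesh. CSF/skull/scalp (and
the WM when it carries no cell model) are coarsened vertically by a factor
2.5; because the grid is structured and conforming, horizontal resolution
is shared across layers, so cell counts are larger than an unstructured
mesh of equal GM resolution would give. A variant with 2:1 horizontally
coarsened (anisotropic) cells lands at ~1750 cells but sits below the
propagation threshold and is used only for resolution studies. When a WM
cell model is active, WM resolution equals GM resolution.

Arbitrary labeled 2D/3D meshes are read and written as Gmsh MSH 2.2 ASCII
with the tissue label in the physical tag; the reader validates
conformity (no duplicated coincident vertices, facets shared by at most
two cells). The mesh I/O layer is deliberately minimal and dependency-free.

## Time integration

Strang splitting: half a step of the cell ODEs, one θ-scheme step of the
linear two-field PDE block, half a step of the ODEs, with θ = 1/2
(Crank–Nicolson) by default and dt = 0.025 ms. In the PDE step v is
θ-averaged while u_e appears once, at the θ-point: eliminating u_e then
reproduces the θ-scheme on the Schur-reduced parabolic operator, which is
what makes the step genuinely second order — θ-averaging u_e as well
couples the step to a stale elliptic state and degrades the pair to first
order. The cell ODEs use forward Euler at dt/2 (the conventional choice
for this model; first order), with an optional midpoint (RK2) substep used
by the verification suite: the manufactured-solution study demonstrates
temporal order ≥ 2 for the splitting with the second-order substep, and
order ~1 with forward Euler, as theory predicts. Gating variables are
clamped to [0,1] only within a 10⁻⁶ tolerance; larger excursions raise an
error naming the step size.

The mass matrix is consistent by default (lumping is available but raises
the propagation threshold in this problem and is not used). The coupled
step matrix is factorized once (sparse LU) and reused every step; a
GMRES+ILU path with relative tolerance 1e-5 and absolute tolerance 1e-50
implements the iterative-solver contract and is verified against dense
direct solves. Probes are sampled by P1 interpolation every step (40 kHz
at the default dt).

## Analysis pipeline

Spikes are upward crossings of a threshold (default −20 mV on v; for u_e
traces an adaptive midrange between the 1st and 99th percentile) with a
2 ms refractory period. Bursts are maximal spike runs with inter-spike
gaps ≤ 500 ms and ≥ 10 spikes. PSDs use Welch's method: Hann window, 50%
overlap, segment length the largest power of two ≤ N/4 (capped at 2¹⁶),
per-segment linear detrending — linear rather than constant detrending
because steeply decaying spectra (β ≈ 5) otherwise acquire a positive
leakage bias of ~0.2 in the fitted exponent. Power-law exponents are
ordinary least squares of log₁₀ power on log₁₀ frequency restricted to a
stated band; β is minus the slope.

The synthetic generator produces Gaussian random-phase signals with
expected PSD ∝ f^-β (amplitudes ∝ f^(−β/2), seeded phases), used to
calibrate the estimator: over 20 seeds the mean fitted exponent is within
0.1 of the target for β = 0…5. These fixtures emulate the spectral decay
of the simulated potentials but none of their nonstationarity (bursts,
onset transients), so estimator calibration says nothing about burst
segmentation — that is tested separately on simulated traces.

White-matter penetration of the wave signature is measured on a column of
depth probes as the contiguous run of depths (from the GM/WM boundary
down) whose high-passed fluctuation amplitude (moving-average subtraction
over 25 ms, edges trimmed) exceeds 20% of the overlying GM probe's. The
high-pass and the contiguity rule separate the travelling-wave signature
from the smooth volume-conduction far field, which otherwise lifts even
deep contralateral probes above a raw-amplitude threshold.

## Problem sizes used by the test suite

The suite runs the point models for 10 s (35 s for the burst-alternation
check) at dt = 0.025 ms, and the 2D tissue experiments for 1 s on the
default slice (~3450 cells), its uniform refinement (~13 800 cells) and an
under-resolved variant (~600 cells); the white-matter cell-model
configuration runs 400 ms on ~6150 cells. These durations are the
package's chosen verification scale: every qualitative claim checked at
this scale (wave ignition, propagation vs failure, attenuation through the
passive layers, anisotropy asymmetry) is established within the first
second of simulated time. Full-length (10 s) tissue statistics and the
seven-run sensitivity family at full duration are run through the CLI
(`epibidomain run`, `epibidomain sweep`).

## Known limitations

- The quasi-static, purely resistive medium assumption is inherited from
  the bidomain derivation; frequency-dependent extracellular media are out
  of scope.
- The first-burst duration of the seizure-like point model is an intrinsic
  property of the transcribed equations and the seed state; it converges
  to ~6.4–6.6 s under both the production and high-accuracy integrators,
  with the spike count and spike rate of the burst being the robustly
  reproducible quantities.
- 3D support covers assembly, solving and I/O on labeled tetrahedral
  meshes; production-scale 3D runs (tens of millions of cells) and MPI
  execution are out of scope.
- The structured mesh generator trades cell-count economy for simplicity
  and determinism; unstructured graded meshes must be supplied externally.
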