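# Methods

`cardioinv` identifies ion-channel drug effects from paired membrane-potential
and cytosolic Ca²⁺ waveforms of stimulated hiPSC-derived cardiomyocytes, and
translates them to an adult ventricular phenotype.  This note documents the
model, the numerical choices, and what the shipped synthetic studies do and do
not demonstrate.

## The base model

A single cardiomyocyte is described by

dv/dt = −Σₓ Iₓ,

with thirteen membrane currents in A/F: I_Na, I_NaL, I_CaL, I_to, I_Kr, I_Ks,
I_K1, I_NaK, I_NaCa, I_pCa, I_bCa, I_bCl and the funny current I_f.  Each
voltage-gated current is the product of a lumped density parameter g_x, the
open probability of a single channel, and a driving term (ohmic v−Eₓ, or a GHK
flux for I_CaL).  The central structural commitment is that **single-channel
function is identical across maturity stages**: two parameterizations of the
model may differ only in densities and geometry.  Gating kinetics are adapted
from the published adult ventricular and hiPSC model families that this class
of models is conventionally built from (fast/late Na⁺ and the K⁺ currents in
Hodgkin–Huxley form; the funny current with a single activation gate; NaK and
NCX with their standard voltage/ion dependences).  Kinetic constants are fixed
in code and are not adjustment targets.

Intracellular Ca²⁺ is resolved in five compartments — dyad (d),
subsarcolemmal space (sl), bulk cytosol (c), junctional SR (s), network SR
(n) — each but the nSR carrying a first-order buffer
(db/dt = k_on·c·(B_tot−b) − k_off·b).  L-type Ca²⁺ flux enters the dyad;
all other membrane Ca²⁺ fluxes enter the SL space; SERCA pumps from the
cytosol into the nSR (forward-only Hill pump, chosen for stability under
large parameter perturbations); inter-compartment exchange is linear
diffusion.

### SR release

Release is availability-limited and directed into the **subsarcolemmal
space**, not the dyad, so that the dyadic concentration remains an almost
pure readout of the L-type trigger:

- open probability p = c_d³/(c_d³ + κ³) (κ = 10 µM),
- J_RyR = p·r·α_RyR·(c_s − c_sl), with availability r obeying
  dr/dt = −J_RyR/(V_cell·β_RyR) + η·p·(1−r),
- a permanently open fraction γ gives J_leak = γ·α_RyR·(c_s − c_sl).

α_RyR is expressed as a lumped conductance in L/ms (so fluxes are in
mmol/ms) and β_RyR in mM; both scale together with the RyR density factor,
which leaves the availability dynamics invariant under density scaling, as
required by the construction.  This mechanism produces graded release (peak
J_RyR follows peak J_CaL on the ascending limb of the clamp curve) and high
gain (∫J_RyR > ∫J_CaL for plateau-range clamps) on both shipped presets;
`cardioinv clamp` reproduces the scan.

### Presets and the maturation map

The **adult preset is the default base model**.  The hiPSC preset is derived
from it by dividing every density-like parameter by (1+λ) with the shipped
maturation factors (λ_Na = 2.00, λ_CaL = −0.53, λ_f = −0.99, λ_χ = −1/3, …),
i.e. p_adult = (1+λ)·p_hiPSC, so the two presets are linked exactly by the
diagonal maturation map Q with Q·p_hiPSC = p_adult.  The surface-to-volume
ratio χ is 0.9 µm⁻¹ (hiPSC, no t-tubules) and 0.6 µm⁻¹ (adult); it is never
free in inversion.  Adult conductance magnitudes sit in the range of the
published adult ventricular models; the RyR/SERCA/buffer/geometry values were
tuned once so that *both* presets beat stably at 1 Hz with physiological AP
shapes (adult APD80 ≈ 340 ms, hiPSC ≈ 410 ms; Ca²⁺ transients of a few
hundred nM riding on a diastolic level of tens of nM) and exhibit graded,
high-gain release.  Both presets share V_cell and volume fractions; only χ
carries the geometric difference, which is the only way geometry enters the
equations.  Buffer on/off rates use standard troponin/SL-site magnitudes; the
jSR buffer uses the calsequestrin equilibrium (K_d 0.65 mM) with deliberately
slowed kinetics — it acts purely as a local Ca²⁺ reservoir and the slower
rates remove the fastest time scale from the system.

Shipped initial conditions are the post-100-beat 1 Hz resting state of each
preset, frozen in `cardioinv._initial_states`.

## Drugs

A drug is a vector ε = 1/IC50 over the targeted currents (restricted to
I_CaL, I_NaL, I_Kr).  At dose D the targeted conductances scale by
1/(1 + D·ε): D = IC50 gives exactly 50 % block.  Because ε acts on the
single-channel level it transfers unchanged between maturity stages; the
adult prediction step simply applies the fitted ε to the adult preset.

## Numerics

The integrator is a fixed-step hybrid scheme, fully compiled (numba): gates
use Rush–Larsen exponential updates; every free and buffered concentration
and the RyR availability use exponential updates of their locally linearized
dynamics (coefficients from the pre-step state, Jacobi splitting); the
membrane potential uses forward Euler.  Purely voltage-dependent factors
(gate steady states and decay factors, GHK coefficients, I_K1/I_NaK/NCX
voltage terms) are tabulated per run on a 0.1 mV grid with linear
interpolation; the interpolation error is orders of magnitude below the
time-discretization error.  This scheme was chosen over an adaptive implicit
solver because the inversion evaluates the model at thousands of strongly
perturbed parameter sets, where robustness and bit-determinism matter more
than adaptive efficiency; halving the step moves APD80 of a paced beat by
less than 0.5 ms (tested), and a cross-check against an adaptive solver
running the plain-Python right-hand side agrees in AP morphology.  Default
steps: 0.02 ms for standalone simulation and clamp protocols, 0.05 ms inside
the drug-study/inversion loop (both model and data use the same protocol, so
the comparison is discretization-consistent).  A diverging state raises a
structured error carrying the last valid time; the cost function converts it
into a penalty (10 per term, dominating any realistic relative difference).

## Cost function and continuation inversion

A fit is scored against per-dose target beats by relative absolute
differences of waveform characteristics: APD30/50/80, CaD20…CaD80, maximum
dv/dt and dCa/dt, Ca²⁺ amplitude and baseline, and the area above the 30 %
repolarization level (int30); optional per-current peak terms exist for
model-to-model fits.  The total cost is Σ_d Σ_j w_dj·H_j², over all doses
including the control.  Exact catalogue definitions of the characteristic
terms are package choices, declared per term in `CostSpec`; amplitude/
baseline terms should be down-weighted for relative-unit (optical) data.
Optional L2 regularization of λ is available but off by default.

The joint fit of control factors λ and drug parameters ε uses continuation:
targets are blended, R^θ = (1−θ)·R(default model) + θ·R(data), so θ = 0 has
the known optimum λ = ε = 0, and θ is stepped to 1 in M increments.  At each
step, budget-limited Nelder–Mead runs start from the incumbent plus random
starts (λ uniform within ±0.2 of the incumbent, clipped to (−0.95, 20); ε
log-uniform within a factor 5).  ε is searched in log space; a zero incumbent
is given a floor corresponding to 1 % block at the *smallest* tested dose —
below detectability everywhere in the ladder, yet close enough that a few
multiplicative steps reach any block expressible within the dose range.  The
full-scale schedule is M = 20 with 63 starts (5 simplex iterations per start,
25 in the last quarter of the steps).  The scaled-down schedule used in the
shipped tests is M = 5 with 8 starts; the acceptance script additionally
applies a 100-iteration simplex polish at θ = 1 and gives the three-channel
(flecainide-like) study a denser search (M = 6, 16 starts) because its
simultaneous CaL/NaL/Kr block makes the cost landscape markedly harder —
these sizes are the package's own desk-scale defaults.  With a
fixed seed and one worker the inversion is bit-reproducible; start
evaluation is order-independent (lowest cost wins, ties broken by start
index), so threaded evaluation gives identical results.

## Identifiability

Membrane currents sampled every 1 ms over one measurement beat form a matrix
A; its right singular vectors are conductance-perturbation directions.  Each
direction v_i is scored by max over ω ∈ {0, 0.1, …, 1} of the cost of
simulating with λ = ω·v_i against the unperturbed model (cost terms APD30/
50/80 and int30, APD80 weighted 5).  Directions scoring below 0.05 span the
unidentifiable space N; the identifiability index of current j is
k(e_j) = ‖e_j − P_N e_j‖₂.  The perturbation beat is the third paced beat (a
compromise between adaptation and cost; the grid and beat choice are package
defaults, stated here because the analysis is mildly sensitive to them).
The default inversion frees only λ_CaL, λ_NaL, λ_Kr (with ε_CaL, ε_NaL,
ε_Kr); the weakly identifiable conductances (I_Na — whose signature lives in
the upstroke velocity, which the identifiability cost deliberately excludes —
I_bCa, I_Ks, I_bCl) stay fixed.

## Synthetic drug studies

The generator reproduces the simulated dose-escalation design: background
perturbation λ_CaL = λ_NaL = λ_Kr = 0.1 on the hiPSC preset, IC50-based block
per dose, 1 Hz pacing, and the sixth beat after each parameter change as the
measurement beat.  Shipped reference drugs: nifedipine (pure I_CaL, IC50
10 nM, doses 3/30/300/3000 nM), lidocaine (pure I_NaL, 10 µM), cisapride
(pure I_Kr, 10 nM), flecainide (I_CaL 25 µM, I_NaL 20 µM, I_Kr 10 µM),
verapamil (I_CaL 200 nM, I_Kr 500 nM).  Ladders other than nifedipine's are
4-point log ladders bracketing the smallest and largest IC50 (IC50/10 …
10·IC50).  Generation is deterministic and noise-free.

What passing recovery tests show: the continuation inversion can identify
IC50s of I_CaL and I_Kr blockers within a factor of ~2 from waveform data
generated *by the same model family* under a modest λ mismatch.  They do not
show robustness to measurement noise, photobleaching, model misspecification
or inter-preparation variability — real optical data add all of these, plus
the min/max mapping of relative units onto the model's range, under which
amplitude/baseline terms carry no information.  The late-Na case is
intrinsically hard: I_NaL barely shapes the paced waveform, so its fitted
magnitude is biased even on clean synthetic data; the package asserts only
correct target ranking for it.

## Known limitations

- Intracellular Na⁺ and K⁺ are fixed; drugs whose effects act through Na⁺
  loading are outside the model's reach.
- The release model's availability mechanism is a stability device, not a
  mechanistic RyR description.
- Drug action is pure conductance block (no state- or use-dependence).
- Spontaneous beating is not modeled; the hiPSC preset is stimulated.
- The identifiability analysis covers membrane currents only, not the Ca²⁺
  handling parameters.
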