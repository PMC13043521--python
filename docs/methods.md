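# Methods

This note documents the generative models, the inference machinery, the
calibration of every quantity that is not part of the tabulated parameter
sets, and the numerical choices that matter.  It states no empirical
result that the test suite or `scripts/acceptance.py` do not themselves
compute.

## Generative models

### Decision (bistable fixed-point) regime

Each of two cortical columns contains two excitatory populations (`e1`,
`e2`) and one inhibitory population (`i`).  Every synaptic pathway is a
second-order kernel

    v̇ = y,   ẏ = H·K·(drive) − 2K·y − K²·v

with excitatory magnitude/rate `He = 3.25 mV`, `Ke = 10 s⁻¹` and
inhibitory `Hi = 22 mV`, `Ki = 200 s⁻¹`.  Seven kernels per column carry
the intrinsic couplings `C1..C7 = 0.1, 0.1, 15, 3, 3, 0.1, 30`; the
extrinsic lateral couplings are `Cee = 0.6` into the target column's
excitatory drive and `Cei = 19` into its inhibitory drive (superscript =
source column).  One printed kernel equation lacks its state-variable
term; we restore the standard `−K²v` form used by all sibling equations.
Firing rates pass through the zero-anchored sigmoid
`S(v) = 1/(1+e^{−r1(v−r2)}) − 1/(1+e^{r1 r2})`, which makes the resting
state an exact equilibrium; its shape parameters are not tabulated and we
use the ERP-DCM convention `r1 = 2 /mV`, `r2 = 1 mV` (config-exposed).

The LFP of a column is the signed sum `y1+y2−y3+y4−y5+y6+y7` exactly as
defined for the model; because those components are labelled EPSP/IPSP, a
potential-based reading is arguable, so `lfp_decision(..., form="v")`
applies the same sign pattern to the `v` states instead (the `y` form is
the default).  The *decision variable* is the e1 post-synaptic potential
`v1` — the state explicitly labelled as e1's PSP — and classification
only ever reads the two `v1` traces, never the LFP.

With these parameters the noise-free balanced model is tristable: a
resting state and two mirror-image choice attractors whose `v1` levels
are ≈ 0.168 mV (winning column) and ≈ 0.006 mV (losing column).  The
decision threshold defaults to the midpoint of the extreme stable levels
(0.08395 mV), derived by the bistability scan in
`mdcm.dynamics.decision_threshold`; it is regime-relative and
reproducible rather than hand-picked.

### Stimulus and input noise

Stimuli are Gaussian current bumps of width 7 ms centred at t = 0 and
truncated at the 2-s offset; column 1 receives amplitude `a + Δ`,
column 2 `a`, and the evidence quality is `ε = Δ/(2a+Δ)`.  The base
amplitude is not printed.  We calibrated `a = 6 nA` so that (i) the
noise-free balanced model stays below the decision threshold
(non-decision), and (ii) across the default evidence ladder
`ε ∈ {0.032, 0.064, 0.128, 0.256}` the model spans the canonical
psychometric range (accuracy ≈ 0.55 → 0.96) with error trials present at
every level and error decisions slower than correct ones.

Input noise is white Gaussian noise (SD 0.02 nA) filtered by AMPA
kinetics (τ = 5 ms), injected independently into the `e1` and `i` drives
of each column (four channels).  Two discretisation conventions of the
white-noise term exist:

* the Itô reading (increment `sd·√dt` per step) gives a filtered current
  with stationary SD `sd/√2 ≈ 0.014 nA`.  Empirically this is an order
  of magnitude too weak to ever flip a decision: across amplitudes
  `a ∈ [0.5, 16]` no error trial occurs at any evidence level at which
  decisions occur at all, which would make quota designs with error
  trials, error-condition averaging and speed–accuracy curves
  unreachable;
* the per-step reading (a fresh `N(0, sd)` draw added per 1-ms step,
  equivalent Itô diffusion `sd/√dt_ref`) gives stationary SD ≈ 0.45 nA
  and produces exactly the expected phenomenology (psychometric rise,
  chronometric fall, slower errors, reachable error quotas).

The trial generator therefore uses the per-step convention, with the
reference step exposed as `DecisionModelParams.noise_step_ref = 1 ms`.
The stand-alone Ornstein–Uhlenbeck primitive `simulate_ou` keeps the
plain Itô convention and its closed-form stationary SD `sd/√2`, which the
acceptance suite verifies.

### Oscillatory (rate-model) regimes

The rate model has three membrane potentials per column (`Ve1`, `Ve2`,
`Vi`) relaxing with `τe = 20 ms`, `τi = 10 ms` and interacting through a
logistic firing-rate function with maximum 70 Hz, threshold `V*` and
steepness `ge = 5 mV` (excitatory) vs `gi = 2 mV` (inhibitory; steeper,
as fast-spiking populations are).  Intrinsic couplings are
`14.96, 14.96, 560, 760, 200, 14.96, 561.02`; lateral couplings are
`Cee = 74.8`/`Cei = 144` (both columns) in the period-doubling preset and
`74.8/144` vs `74.8/32` (asymmetric) in the chaotic preset.  The LFP is
`−Ve2`.  Epochs are 1.5 s, recorded after a 5 s on-attractor transient
from a fixed, minutely desymmetrised initial state (symmetric states
never desymmetrise in a deterministic symmetric system).

The baseline rate `r0`, threshold `V*` and the constant drive `I` are not
printed and were calibrated by the regime scan
(`mdcm.dynamics.regime_scan`): `r0 = 0 Hz` and `V* = 25 mV` are shared by
both presets; scanning the drive then locates fixed-point, limit-cycle,
two-band and chaotic windows.  Within those windows the drives were
pinned by the reported dynamical character of each ground truth — the
printed Lyapunov exponents are the only observables that identify the
missing drive — giving `I = 327.5 mV/s` (two-band attractor at the
chaotic edge, exponent ≈ 0.28 at the diagnostic settings) and
`I = 802.8 mV/s` (broadband chaos, exponent ≈ 17.0).  A strictly
period-2 limit cycle has exponent exactly 0, so a *positive* reported
exponent for a period-doubled regime is itself only attainable at the
two-band chaotic edge; finite-horizon estimates there are
method-dependent, which is why the acceptance suite asserts the sign and
two-band structure for that regime rather than the third decimal.

## Inversion (variational Laplace)

Only extrinsic connections are estimated; intrinsic parameters stay at
their known ground-truth values.  Each present connection carries a
log-scaling `θ ~ N(0, 1/8)` with effective strength
`prior mean × exp(θ)` (positivity by construction).  The observation
model is the deterministic forward simulation plus i.i.d. Gaussian noise
with log-precision `λ ~ N(4, 1)`; data are source-level LFP with an
identity lead field and unit gain (peak-normalisation is available behind
`normalize_data` to study amplitude degeneracy, off by default).

The optimiser alternates a damped Gauss–Newton update of the Gaussian
posterior over θ (central finite differences, step 1e-3, integrated as
one batched ensemble) with a scalar Newton update of λ, accepting a step
only if the free energy `F = accuracy − complexity` does not decrease;
λ is kept within six prior SDs so that an exactly-fitted deterministic
epoch cannot drive the precision to infinity.  Accuracy is the expected
log-likelihood under the Laplace posterior (residual sum of squares plus
the posterior trace correction); complexity is the KL divergence from
prior to posterior over θ and λ, hence non-negative at every iteration.
Stopping: `|ΔF| < 1e-2` or 64 iterations (both exposed).  Because steps
are accepted against the free energy linearised at the previous iterate,
re-linearising after acceptance can lower the recorded F by parts in
1e5; the trace is monotone up to that rounding.

Connections can share a tie group: the `lateral_tied_ei` architecture
estimates one common scale for both inhibitory laterals, preserving their
(possibly asymmetric) prior ratio — the workaround needed when a toolbox
cannot scale the two inhibitory laterals independently.  The default
model space uses the untied architectures.

The free-energy landscape of multistable regimes is multimodal: from the
prior-mean start the lateral candidate frequently converges to a poor
local optimum on decided trials while an asymmetric candidate fits
easily.  The package therefore supports explicit extra initialisations,
and decision-regime studies use three starts per candidate — the prior
mean plus two mirrored "choice-biased" patterns (excite the favoured
column's e1 drive, damp the other's, lift its inhibitory drive) — the
structured counterpart of random multistart.  With a single prior-mean
start the lateral model can lose to the forward–backward model on
individual trials; the landscape, not the evidence, is at fault.

## Model comparison and averaging

Random-effects BMS fits a Dirichlet over model frequencies with symmetric
prior count `α0 = 1` and tolerance 1e-6; exceedance probabilities use the
exact Beta tail for two models and 10⁶ seeded Dirichlet draws otherwise.
Fixed-effects comparison sums free energies.  BMA samples each trial's
Gaussian θ posterior (uniform trial weights by default;
evidence-proportional weights optional), maps draws through `exp` and
reports mixture mean/SD on the strength scale.  Conditions (correct /
error / all trials) are separate BMS+BMA runs sharing one inversion
matrix.

## Pipeline and evaluation scales

`run_experiment` chains the stages with a single master seed; every
internal Monte-Carlo draw is seeded, so reports reproduce bit for bit.
Reconstruction re-simulates with the *averaged* strengths (provenance
recorded in the report) on the same seed lists as the ground-truth run,
giving paired psychometric/chronometric comparisons, the accuracy-curve
curvature sign (mean second difference across evidence levels), and — in
the oscillatory regimes — timecourse RMSE, Lyapunov exponent and
peak-class comparisons.  A sampling-rate diagnostic
(`sampling_rate_experiment`) inverts one epoch decimated to e.g. 500 Hz
and 10 kHz and reports recovery per rate (reported, not asserted: it
depends on the inversion settings).

The test suite exercises reduced designs chosen to finish in minutes on
one CPU: psychophysics properties on 300 attempts per evidence level;
model identification on 20 lateral-generated trials per regime
(deterministic rate epochs are replicated, so their inversions dedupe to
one per architecture); Lyapunov diagnostics on 60 s horizons (renormalise
every 1 ms, first 20% discarded as transient; the 1.5 s data epochs are
far too short for stable exponents).  The full-scale design — 1600
decision trials, 400 epochs per rate regime, 1000 reconstruction
simulations per evidence level — is expressed by the defaults of
`ExperimentConfig` and `TrialSetSpec` and runs unchanged, just longer.

## What the generator does and does not emulate

Trials are source-level LFP from known columns: there is no sensor
forward model, no volume conduction, no delays, no inter-trial parameter
drift, and the observation noise of the inversion is the only mismatch
channel besides the input noise itself.  Passing tests therefore show
that the inference machinery behaves as specified *under ideal
observation conditions*; they do not show robustness to lead-field
error, artefacts or non-stationarity in real recordings.  Within the
multistable regimes, parameter recovery is reported rather than asserted
— the whole point of the bench is that selection can succeed while
strengths drift into asymmetry.

## Known limitations

* Finite-horizon Lyapunov estimates at the two-band chaotic edge are
  sensitive to rounding-level perturbations of the trajectory; exponents
  are comparable only at identical numerical settings.
* The λ (noise-precision) posterior uses a point-Laplace treatment; no
  temporally correlated noise models are implemented.
* Forward–backward laminar targeting is a convention (forward → e1
  drive; backward → e1 and i drives): it only affects non-generating
  candidates, so model comparison remains well posed, but absolute free
  energies of those candidates depend on it.
* The sampling-rate diagnostic inverts noise-free epochs from the truth
  initialisation; it probes identifiability, not estimation difficulty.
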