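# Methods

## Model

One enzyme (FtsI as the model septal transpeptidase) moves on a 1D axis
along the septum; one FtsZ filament of `N_fil` = 50 subunits of
`L0` = 5 nm treadmills rightward at speed `V_Z`.  Each live subunit
carries a truncated inverted-parabola binding well

    U(x) = -U0 * (1 - ((x - x_c)/a)^2),   |x - x_c| <= a,   else 0,

with half-width `a` = 2.5 nm so adjacent wells tile the filament interior
without barriers; the enzyme feels the well of the nearest live subunit
(ties toward the smaller index).  Removing the shrinking-end subunit
leaves a flat ~5 nm stretch — the time asymmetry that rectifies
diffusion.  The enzyme's dynamics are overdamped Langevin with mobility
`D` (k_BT = 1), i.e. drift `D f(x)` and diffusion `D`.

Assumptions: treadmilling is a deterministic per-filament clock (one
subunit off, one on, every `L0/(V_Z dt)` steps; filament length and speed
constant within a trajectory; ensemble-level speed variability is modeled
by drawing `V_Z` per trajectory from a truncated Gaussian with ~30% CV
where wanted); open boundaries on both sides; no explicit protein relay
(FtsN/FtsA/FtsEX are lumped into the effective well), no GTP chemistry,
no membrane geometry.

Default parameters (units nm, s, k_BT): `D` in [1e3, 3e5] nm^2/s
(0.001–0.3 um^2/s, the membrane-protein range; reference 0.04),
`U0` in [0, 20] (reference 10, ~uM-range dissociation), `V_Z` in
[8, 100] nm/s (in vivo ~20–40), `t_max` 120 s for run statistics and
600 s for lifetimes.

## Integration

The production kernels use a Metropolis-adjusted Langevin step (MALA):
the Euler–Maruyama proposal `x' = x + D f(x) dt + sqrt(2 D dt) eta` is
accepted with the usual Metropolis–Hastings ratio.  The reason is
accuracy of *rare-event* statistics: the mean escape time from a 10 k_BT
well carries an Arrhenius factor, and at any affordable step size plain
Euler inflates the in-well stationary variance by `2/(2 - q)` (with
`q = 2 D U0 dt / a^2`), which at the reference point (D = 0.04 um^2/s,
dt = 5e-6 s) shortens the single-well escape time to ~10 s against the
continuum value of 37.8 s computed by double quadrature; an in-well-exact
Ornstein–Uhlenbeck update errs the other way (~96 s) because it treats
the well as unbounded within a step.  MALA, whose stationary law is
exactly Boltzmann, reproduces 35.7 ± 7 s at the same step.  The
acceptance suite checks the within-well position distribution against
the Boltzmann weight by KS distance.

The time step is chosen so the RMS free-diffusion step stays at a quarter
of the well half-width (`choose_dt`), giving ~5e-6 s at D = 0.04 um^2/s
and proportionally larger steps for slower diffusers; runs refuse to
start if the noise step exceeds `0.8 a` (edge crossings would be
unresolvable).  `ratchet.step_enzyme` retains the plain Euler–Maruyama
form as the readable reference discretisation; kernels and reference are
pinned against each other through distributional tests (step variance,
Boltzmann occupancy, free-diffusion MSD).

A trajectory ends at `t_max` or once the enzyme has stayed more than
100 nm beyond both filament ends for over 1 s (free diffusion far from
the filament carries no further information).  The exact first passage
beyond that margin is recorded at step resolution and defines the bound
lifetime (mid-filament starts; censoring at `t_max` is flagged, and
censored ensembles are summarised both naively and by Kaplan–Meier
restricted means).

## Run classification

A trajectory is scored *persistent end-tracking* from its recorded
series using the single-molecule criteria: distance between enzyme and
the tracked end below 100 nm, sustained for at least 4 s.  Three
interpretation choices, each exposed as an `EndTrackCriteria` field:

- **Analysis cadence (1 s).**  The criteria mirror the experimental
  analysis, which images at 1 s/frame; they are applied to the
  trajectory resampled at that cadence, so sub-frame excursions invisible
  to a measurement do not break a run.
- **Unidirectionality (20 nm backtrack).**  A run closes at its forward
  maximum once the enzyme drops more than ~4 subunit lengths below it;
  ground lost against a receding end at that scale means the ratchet
  step failed.  The same 20 nm is the failure cutoff in the catch-up
  time estimator, keeping simulation scoring and theory consistent.
- **Scope (first run).**  Only the run that starts at the trajectory's
  shrinking-end initial condition is scored — the quantity the
  closed-form statistics describe; `scope="any"` credits later
  re-captures instead.

A run must also show net forward motion of at least half the end's
advance (`min_follow_fraction`), which excludes an enzyme that merely
sits inside the distance window while the end recedes past it.

## Closed-form theory and time scales

`analytic` implements the per-step survival
`P = exp(-(tau_Z/tau_D + tau_C/tau_Z))`, mean step count
`<N> = tau_D tau_Z/(tau_Z^2 + tau_C tau_D)` (the continuum limit of the
geometric sum, kept separately as `mean_steps_discrete` and verified
against brute-force summation), run length `<L> = L0 <N>`, duration
`<T> = <N> tau_Z`, and the optimum `V* = L0/sqrt(tau_C tau_D)`.

The two time scales come either from quadrature (`tau_D_theory`: MFPT
from the well bottom to ±100 nm, the same distance that terminates runs;
`tau_C_theory`: conditional exit time of free diffusion across the 2.5 nm
to the next well edge with a 20 nm failure cutoff) or from targeted
micro-simulations (`estimate_tau_D`, single static well, first passage;
`estimate_tau_C`, successful catch-ups only).  At the reference point the
measured values are tau_D ≈ 40–60 s and tau_C ≈ 5–7 x 1e-4 s, matching
the magnitudes quoted for this regime.

## Known quantitative caveats

Absolute processivity levels are exquisitely sensitive to the well-escape
rate (exponential in `U0` and in any discretisation bias).  With accurate
integration of the stated model, the enzyme exits the end well on ~0.2 s
time scales and accumulates lag through repeated catch-ups; the
simulated per-speed propensities therefore decline more steeply with
`V_Z` than the published curve for this system (whose quoted dwell time,
~60 s, exceeds the continuum value of the stated potential), the total
persistent fraction in the 10-speed reference sweep comes out near 45%
rather than ~66%, and the mean-run-distance optimum shifts above the
~30 nm/s seen in that work (the closed-form optimum with *measured* time
scales does land at ~25–40 nm/s).  Similarly, at the 1 s analysis cadence
fast diffusers (D > 0.1 um^2/s) still score as end-tracking at slow
treadmilling speeds — their lose-and-recapture churn is invisible between
frames — even though their continuous-time bound lifetimes are correctly
short.  Trends and identities that do not hinge on absolute escape rates
(duration monotone in `V_Z`, speed locking to `V_Z`, growing-end failure,
the weak-potential boundary near 4–5 k_BT, the ~70% lifetime drop of a
slow enzyme between 8 and 25 nm/s, `<L>/<T> = V_Z`) are reproduced and
tested.

## SMT pipeline

Localization tables (frame, x, y, intensity, sigma, uncertainty) are
filtered (intensity ≥ 300, sigma within 60–300 nm), linked by greedy
mutual-nearest-neighbour assignment (300 nm distance threshold,
independent of gap length; up to 15 dark frames), projected onto a
division-ring circle fitted by weighted algebraic (Kasa) least squares
(cross-checked against scikit-image's circle model; three points give the
circumscribed circle exactly), and unwrapped via phase-unwrapped angles
to arc length.  Segments (≥ 4 points, ≥ 4 s) are summarised by the
line-fit observables {v, d, l, r} and the noise-to-signal ratio
`R = r/d`; `R ≤ 0.4` classifies processive, `d < 1 nm` maps to an
infinite-R stationary sentinel.  Segmentation accepts user breakpoints
(the analogue of manual segmentation) or an automatic recursive
binary-split changepoint finder (penalty from a second-difference noise
estimate) — the latter is an extension beyond the manual procedure.

Speed distributions are deconvolved by least-squares fitting of a
two-component log-normal CDF to the empirical CDF (multi-start;
components ordered mu1 < mu2; 200 bootstrap refits for parameter
spreads; degenerate or coincident components flagged).  The slow
population is stripped by removing samples with probability equal to the
slow component's posterior share of their Freedman–Diaconis display bin,
100 independent rounds.  MSDs are time-averaged over overlapping pairs
with lags capped at a quarter of the track length, and fitted with
`MSD = 4 D t^alpha + D0` under bounds `D ≥ 0`, `alpha ∈ (0, 2]`,
`D0 ≥ 0`; `D0` absorbs the localization-noise floor `4 sigma_loc^2`.

## Synthetic data

Generators emulate the pipeline's inputs: directional or diffusive
motion on a 1.2–1.4 um ring at 1 s/frame with isotropic Gaussian
localization noise and random frame drops; two-population log-normal
speed samples; 2D Brownian tracks at 30 ms/frame with localization
noise.  They are deterministic under a seed.  What they do not emulate:
blinking photophysics beyond frame drops, camera noise, localization
bias, sub-diffusive (alpha < 1) ground truth — so pipeline tests
demonstrate estimator correctness on ideal data, not robustness to
instrument artifacts.

## Problem sizes

The test suite runs the reference sweep at 100 trajectories per speed
(10 speeds, `t_max` 120 s), lifetime ensembles at 200 per speed, and
phase-diagram cells at 40–50 trajectories with 15–20 s horizons; the
acceptance script uses the same sizes with 100 per cell on the
weak-potential boundary rows.  Mixture-fit tests use 3000–5000 samples
with 30–50 bootstrap rounds.  These sizes keep full runs in the
minutes-to-quarter-hour range on a single core.
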