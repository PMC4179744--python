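# Methods

This note documents the models, the synthetic-data conditions, the numerical
choices, and the limits of what the test suite establishes.

## Task geometry and trial tables

A trial presents a cue at lateral position `x` ∈ [−100, +100] mm (0 = display
center) and schedules a target at onset `f(x)` ms after trial initiation,
where `f` is the hidden generating polynomial.  The participant fires a
bullet with 300 ms travel time at a target visible for 150 ms, so a shot
fired at time `t` hits iff `onset ≤ t + 300 ≤ onset + 150`.  All analyses
consume a *trial table* (CSV schema
`trial,phase,x_mm,onset_ms,response_ms,trial_type,hit`), where
`response_ms` is the interception-time observation — the quantity the
generating function predicts.  The simulated observer's hit flag is derived
by assuming it fired 300 ms before its (noisy) arrival time; an agent whose
`response_ms` tracks the onset closely therefore hits whenever its noise
leaves the arrival inside the 150 ms visibility window.

Generating functions (coefficients ascending, ms·mm⁻ᵈ):

| context | constant | linear | quadratic | cubic |
|---|---|---|---|---|
| single-session experiments | — | 1250 − 5x | 1700 + 0.5x − 0.1x² | 1500 − 3ax + ax² + ax³, a = 1/1500 |
| switching experiments | 1350 | 1350 + 7x | 2100 + 0.1x − 0.15x² | — |

## Synthetic participants

The generator emulates the study conditions: stimuli serially uncorrelated
and uniform over the span; single-function sessions of 170 trials (50
training burn-in, then 60 test and 60 training trials strictly alternating,
drawn from disjoint regions); switching sessions of 500 trials with the
function replaced after trials 100 and 250; responses = active function +
zero-mean Gaussian noise (canonical sds 10–400 ms).  The observer is
*omniscient*: it knows the active function and its parameters and switches
instantly.  Four group orders (C→L→Q, Q→L→C, C→Q→L, Q→C→L) cover all six
ordered transitions between the three function classes.

What this does **not** emulate: human learning dynamics (lag after
switches, drift, trial-by-trial updating), heteroscedastic or non-Gaussian
response noise, motor constraints, or any dependence of responses on
feedback history.  Passing tests therefore establish properties of the
*analysis machinery* under its stated assumptions — not claims about real
participants, whose data are not available.

Train/test region boundaries are published only graphically, so they are
configurable presets: an *interpolation* layout (train [−100,−60] ∪ [−20,20]
∪ [60,100], test in the two gaps; default for the quadratic session) and an
*extrapolation* layout (train [−60,−10] ∪ [10,60], test on the flanks;
default for linear and cubic).  Every analysis takes regions as input, so
none depends on this choice.

## Experiment-1 model zoo

All families are fit by maximum likelihood to the post-burn-in training
trials only and evaluated on test-trial likelihoods:

* **Polynomial regression** of each relevant degree (OLS).  Predictive
  variance propagates the coefficient covariance, `v' (X'X)⁻¹ σ̂² v` with
  `v = (1, x*, …, x*ᵈ)` — the linear case reduces to
  var(θ̂₀) + var(θ̂₁)x*² + 2x* cov(θ̂₀,θ̂₁) — *plus* the residual
  (observation) variance.  The observation term is a deliberate choice:
  without it the test likelihood of a near-perfect fit is degenerate, and
  test responses do carry response noise.
* **Interpolation heuristic**: an independent line per training region;
  between regions, linear interpolation between segment edge values with
  variance `w²·varL + (1−w)²·varR` (edge estimates are independent — the
  segments see disjoint data) plus the weight-averaged residual variance;
  outside the trained range, flat flanks at the nearest boundary value.
* **Extrapolation heuristic**: the same segments extrapolated; a flanked
  central gap uses each neighboring line up to their intersection when that
  intersection falls inside the gap, else falls back to interpolation
  (parallel lines always fall back).  Nearest-segment ties at equidistant
  points resolve to the lower-x segment.
* **Squared-exponential GP** with three hyperparameters (length scale,
  signal sd, noise sd — a two-parameter SE kernel cannot set its output
  scale), prior mean equal to the training mean.  Hyperparameters maximize
  the exact log marginal likelihood via a 5×5×5 log-spaced multistart grid
  (length scale from span/30 to 3·span; signal and noise sds scaled to the
  response sd) refined by L-BFGS-B in log space; non-convergence falls back
  to the best grid point with a warning.  Predictive variance includes the
  noise term so GP test likelihoods are commensurable with the other
  families.

Model comparison uses (i) summed test negative log likelihood differences
against the generating-function polynomial (positive = worse) and (ii)
marginal likelihoods under uniform parameter priors over large boxes
(±10000 ms constant, ±100 ms/mm linear, ±10 ms/mm² quadratic, ±1 ms/mm³
cubic; heuristics use the constant/linear box per segment), reported as
Bayes factors on the 2 ln K scale (0–2 not worth a mention, 2–6 positive,
6–10 strong, >10 very strong; magnitudes are categorized and the favored
side reported when the sign is negative).

**Numerical integration.**  At realistic noise the test likelihood occupies
a vanishing fraction of those prior boxes (the constant-axis posterior width
is ~σ/√n ≈ 15 ms against a 20 000 ms box), so fixed uniform grids cannot
resolve it.  The package therefore evaluates the same uniform-prior
integral with (a) deterministic Gauss–Legendre tensor quadrature in the
likelihood's whitened coordinates (±10 likelihood-sds; 240/120/80 nodes per
axis for 1/2/3 parameters), applying the box as an indicator and its volume
as the prior normalizer, for families with ≤ 3 parameters; and (b) seeded
importance sampling (10⁵ draws from a two-component Gaussian proposal
around the likelihood maximizer, with a defensively wide component and
flat-direction variances capped at the box scale) for the 4–6-parameter
heuristics, with a log-scale standard error reported.  Exactness checks:
the constant-model marginal matches its closed form through the Gaussian
cdf; doubling every range lowers each log marginal by exactly ln 2 per
dimension; grid and Monte-Carlo routes agree within 3 standard errors.
The likelihood given parameters uses the plug-in MLE residual sd from the
training fit (per-branch for the heuristics); only mean-function parameters
are integrated.

## Bayesian model selection (switching sessions)

Candidates are the nested polynomials of degree 0, 1, 2.  Coefficient
priors are independent Gaussians with means (5000, 50, 5) for the degree-0,
1, 2 terms — deliberately far from every veridical value — and sds ten
times those means, so the prior location is immaterial (property-tested:
inflating all sds ×10 moves every posterior by < 0.05).  Coefficients
integrate out in closed form; computationally each window uses one thin SVD
of the sd-scaled design, after which the marginal density is O(rank) for
every noise value, and the sliding-window sweep batches the SVDs over all
451 frames.

The noise sd is marginalized under a uniform prior on (0, 5000] ms using
500 *log-spaced* quadrature nodes with non-uniform trapezoid weights (the
weights, not the node placement, carry the uniform prior).  Log spacing is
essential: the σ-likelihood peak has width ≈ σ/√(2n), so 10-ms linear
spacing misses the peak entirely at σ ≈ 10 ms, while log spacing resolves
it at every noise level; refining 500 → 5000 nodes moves fixture marginals
by < 10⁻³ nats.  All accumulation is in log space with a final softmax.

Windowed analysis: 50-trial moving windows, step 1 (451 frames per
500-trial session), each frame *anchored at its last trial* so time courses
are causal.  Windowed MLE coefficient trajectories are least-squares
solutions accepted when inside the search boxes (±10000, ±100, ±10 per term
degree) and boundary-constrained otherwise, with the noise sd re-estimated
in every window; trajectories may be smoothed with a discrete Gaussian
kernel (sd = 5 frames, truncated at 3 sd, edge-renormalized).  Smoothing is
applied to parameter trajectories only, never to posteriors.

## Acquisition analysis

The acquisition time of a transition is the smallest k ≥ 1 such that the
frame anchored at trial switch+k gives the incoming function's posterior ≥
threshold (0.33 = chance by default; 0.5, 0.66, 0.99 in the sweep).  Times
never reached before the segment ends are censored; censored times are
excluded from means and their count reported.  The Monte-Carlo baseline
simulates the omniscient observer across the four group designs and the
seven noise sds, reruns the full windowed analysis per run, and aggregates
per transition; pair differences are reported as *complexifying minus
simplifying* (e.g. CL − LC) with the orientation stored explicitly, and
participant-style differences are compared to the baseline difference with
a two-tailed one-sample t-test.

**Observed baseline behavior.**  At sd 10, W = 50, threshold 0.33 the
baseline acquires the linear function much faster after constant→linear
than the constant after linear→constant (≈12 vs ≈37 trials), and likewise
for the linear↔quadratic pair (≈24 vs ≈28) — the straddling window's
mixture reveals an incoming *more complex* function early, because the
complex model can absorb the old simple data while fitting the new points.
The constant↔quadratic pair does **not** show this inversion (≈25 to the
quadratic vs ≈23 to the constant, stable across seeds): those two functions
are separated by a large offset almost everywhere, so mixture windows are
discriminated by which function explains more points rather than by
curvature, and the marginal-likelihood complexity penalty then mildly
favors the incoming *simpler* model.  The complexity asymmetry of the
window analysis is thus a property of value-range overlap between the old
and new functions, not of the pair's complexity ordering per se.  Mean
acquisition times vary by less than ~20% across the seven noise sds
(max/min ≈ 1.12–1.20) because the noise level is re-estimated in every
window.

## Default problem sizes

The test suite and acceptance script use: 100 seeded replicates per
condition for selection-rate and recovery properties; 25 baseline runs per
group (100 sessions) for the sd-10 asymmetry; 15 runs per group per sd (420
sessions) for the noise-insensitivity ratio, a size at which the measured
max/min ratio is stable to ~±0.04; 20 random fixtures (n ≤ 8, degrees 0–2)
for the analytic-vs-numeric marginal check at 10⁻⁶ relative tolerance,
whose brute-force oracle integrates likelihood × prior directly on a
whitened Gauss–Legendre tensor grid.

## Known limitations

* The omniscient observer brackets, but does not model, human learning;
  acquisition-time baselines quantify analysis-induced asymmetries only.
* The marginal-likelihood machinery assumes Gaussian response noise; heavy
  tails would bias both the posteriors and the noise marginalization.
* Region presets and group orders are package defaults standing in for
  details published only in figures; every consumer takes them as inputs.
* GP evidence integrates kernel hyperparameters on a coarse log grid
  (21³ nodes) and is reported for completeness, not precision.
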