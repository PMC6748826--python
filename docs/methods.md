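# Methods

`uffclamp` models and analyzes ultrafast force-clamp (UFFC) optical-trap
recordings of single myosin molecules interacting with an actin filament held
between two trapped beads.  This note describes the models, the default
parameters and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that a user may want to
revisit.  All quantities are in seconds, nanometers, piconewtons, and s^-1;
hindering load (force opposing the working stroke) is positive.

## Mechanochemical kinetic model

A `KineticScheme` is a continuous-time Markov chain.  Attached states carry a
mean lever-arm position contribution (nm); detached states are absorbing for
a single interaction.  Transition rates follow the Bell form

    k(F) = k0 * exp(F * d / kT),      kT = 4.11 pN nm (~25 C),

with the signed distance parameter `d` setting the force sensitivity; an
optional second distance applies under assisting (negative) load so that
pathways with asymmetric force dependence (stroke reversal, fast detachment)
can be represented.  State paths are drawn by the first-reaction Gillespie
rule: one candidate exponential waiting time per outgoing transition, the
minimum wins.  This reproduces the analytic branching fractions
`k_ij / k_sum` and Exponential(`k_sum`) state dwells, which the test suite
verifies against closed forms.

### The stroke-first preset

Binding enters a short-lived, weakly bound pre-stroke state that either
detaches at a strongly force-dependent fast rate or performs the ~6 nm
working stroke; phosphate release follows the stroke; phosphate rebinding
(pseudo-first-order in [Pi]) re-enables stroke reversal; ADP release adds a
~1 nm second phase; ATP binding (rate-limiting at 1 uM MgATP) terminates
full-cycle events.  Printed anchors fix the load-bearing parameters:

| transition | default | anchor |
|---|---|---|
| fast detach | 500 s^-1 at 0 pN -> 5000 s^-1 at 4.5 pN (d = 2.10 nm) | published range of the short-lived state's detachment |
| working stroke | 300 s^-1, d = 1.2 nm | pre-stroke lifetime ~300 us under moderate (3 pN) hindering load |
| Pi release | 17 s^-1, force-independent | solution biochemistry (11.6-17 s^-1) |
| Pi rebinding | 30 s^-1 per mM | chosen so dip effects appear at 10 mM and vanish at 0 mM |
| stroke reversal (initial) | 12 s^-1, d = 1.55 nm (0.3 nm assisting) | asymmetric force dependence of the intermediate detachment class |
| stroke reversal (post-rebound) | 150 s^-1, d = 1.55 nm | rebinding re-enables reversal without full cleft reopening |
| post-reversal detach | 12-25 s^-1, d = 1.5 nm | post-reversal pre-stroke lifetime ~1 ms under load |
| ADP release | 60 s^-1 | second-phase completion time |
| ATP binding | 7 s^-1 at 1 uM MgATP | slow detachment class 6-8 s^-1 |

Phosphate rebinding enters a *distinct* rebound state with its own, stronger
reversal pathway.  Whether rebinding restores the original post-stroke state
is an open mechanistic question; the distinct-state choice implements the
observation that the post-reversal lifetime (~1 ms) exceeds the initial
pre-stroke lifetime (~300 us), i.e. rebinding does not fully reopen the
actin-binding cleft.  The published record fixes ranges, not a complete rate
table, so the preset reproduces the directional phosphate signatures, not
exact curve shapes; every rate is configurable and schemes round-trip
through YAML files.

Two printed anchors are mutually inconsistent at face value: a 300 us
pre-stroke lifetime "under load" cannot hold at 4.5 pN if fast detachment
alone reaches 5000 s^-1 there.  The preset honors the concrete 500->5000
endpoint calibration and realizes ~330 us at 3 pN (~160 us at 4.5 pN).

### The phosphate-first preset

The alternative ordering places phosphate release and rebinding between
binding and the stroke.  For that ordering to produce the observed
sub-millisecond stroke, its release step must be very fast (10,000 s^-1
here, the scale required of any intermediate step); rebinding is set
diffusion-limited (2000 s^-1 per mM).  Its discriminating prediction —
a phosphate-dependent slowing of the observed stroke rate — is what the
comparison module measures.  Separately, a release-first variant that keeps
the published 17 s^-1 release rate sends only 0.34-3.3% of attachments
through the stroke (17/(17+k_detach) for detachment at 5000-500 s^-1),
far below the observed full-cycle fraction; this closed form and its
Monte-Carlo cross-check are part of the acceptance suite.

## Synthetic trace generator

While unbound, the trap (and filament) moves at `applied_force /
drag_coefficient`, reversing at each endpoint of the 200 nm excursion.  The
default drag (4.5e-5 pN s/nm) makes one leg last 3 ms at 3 pN, so the
endpoint-triggered feedback pauses (2 ms, trap frozen, applied force off)
occur twice per 10 ms cycle, as in the instrument.  Because pauses trigger
only at excursion endpoints, they never occur while myosin is bound; about
40% of recorded time is paused at 3 pN, as in the real recordings.
Attachments begin as a Poisson process while unbound.  On binding, the
position relaxes exponentially (50 us) to the series-elastic stretch
`F / link_stiffness` (2 pN/nm) continued in the direction of motion, and
each occupied state adds its position value plus one per-interaction
Gaussian jitter draw (SD 0.1 nm).  Events beginning on legs moving against
the stroke polarity are hindering-loaded; the signed force enters every
rate.

Measurement noise is white Gaussian on position (1 nm) and force (0.05 pN)
plus a low-pass Ornstein-Uhlenbeck position term (SD 2.0 nm, correlation
0.25 ms) emulating the Brownian wander of the dumbbell under feedback.
Purely white noise at 250 kHz cannot reproduce the instrument's
detection-limiting velocity fluctuations — after Gaussian smoothing its
velocity contribution is negligible — so the OU term carries the
low-frequency weight that actually limits arrest detection.  The OU/white
amplitudes were calibrated once so that the empirically calibrated minimum
detectable event lengths land near the published per-force deadtimes
(1.47/1.00/0.68/0.46/0.32 ms at 1.5/2.25/3/3.75/4.5 pN, vs 2.7/1.25/0.73/
0.65/0.5 ms published; 0.5-0.95x, monotone) while long arrests are not
split by false unbinding at >= 3 pN.  Brownian bead dynamics, bead
rotation, hydrodynamic coupling, dual-head attachment, and trap-stiffness
calibration are not modeled; conclusions about real data should rest on the
analysis-chain properties the tests establish (detection efficiency,
deadtime-corrected inference, ensemble quantification), not on the noise
realism of the generator.

Instrumental drift is applied as a force baseline `offset + slope*t +
eod_slope*(x + excursion/2)` (defaults 1 pN/hour and 0.002 pN/nm, inside
the reported instrumental ranges), with the pause insertion shifting
subsequent samples in time; ground-truth event times shift accordingly.

## Drift and slope correction (DSC)

During each feedback pause the applied force is off, so the recorded force
reads the zero-force baseline F0.  Per pause, F0 is the mean of the last
1.5 ms; pauses are classified top/bottom by trap position; the deflector
slope is `(F0_high - F0_low) / (x_high - x_low)` (the printed form of this
relation is typographically garbled in the source methods; this reading —
the baseline difference over the excursion — is the only dimensionally
sensible one).  Estimates are rolling-averaged over 20 pauses and linearly
interpolated in time offline (the real-time system applies the latest
estimate; interpolation is strictly more accurate for re-analysis).  The
corrected force is `F - F0(x, t)`; pause samples stay flagged and are
ignored downstream.  Injected 1 pN/hour drift plus a 0.002 pN/nm slope are
corrected to below 0.05 pN mean residual on clamped segments.

## Event detection

The leading-bead trap position proxies the filament position.  Velocity is
computed by convolving position with a Gaussian-derivative kernel (one
pass; SD 160-800 us, heavier at lower force where unbound motion is
slower), and maximal spans with |v| below a threshold are candidate
events.  Pause spans are arrest-like (frozen trap), so any candidate span
containing a pause sample is discarded — genuine attachments cannot
contain pauses because pauses trigger only at the excursion endpoints,
which are reached only while unbound.  Spans touching the trace boundaries
are discarded (unknown start or end).

The threshold is a fraction theta of the median unbound speed, chosen as
the largest grid value (<= 0.5, the noise-free tie-break) for which the
count of false events (sub-threshold spans >= deadtime) on a binding-free
trace stays at or below 1% of the expected event count; smoothing
auto-selection picks the smallest width admitting such a threshold.  The
published criterion cites an unprinted statistical estimator; this
empirical surrogate on binding-free traces is the reproducible
operationalization.  Start/end times carry the analytic filter-delay
correction `sigma * Phi^-1(1 - theta)` (zero at theta = 0.5).  Event
direction comes from the sign of the recorded clamp force during the
event, which is the motion direction at binding.

Two raw-position refinements correct hindering-event boundaries:
a binding that occurs shortly after a trap direction switch merges with the
switch's velocity dip, so a start whose position sits well above the early
block-mean minimum (48 us blocks) is advanced to that minimum's first
block; symmetrically, an end already on the post-release departure is
pulled back to the last block at the attached plateau (applied only to
spans of at least 3 ms: on near-deadtime spans the plateau estimate is
noise-dominated and the trim would systematically shorten durations).
These trims use 6 nm trigger and 3 nm settle margins (3x and 1.5x the
block-mean noise).
Measured one-to-one against ground truth, start-time RMS errors are
~400/390/230/100/70 us at 1.5/2.25/3/3.75/4.5 pN; the per-force sigma_t
defaults (550/360/290/170/110 us) are these calibrated values with an
estimation margin.  Events shorter than the per-force published deadtime
(2.7/1.25/0.73/0.65/0.5 ms) are excluded, and the same deadtime truncates
the dwell-time likelihood.

`calibrate_deadtime_sigma` measures the actual minimum detectable arrest
(95% detection of injected rigid arrests) and the start-time SD for any
instrument configuration, which is how the defaults above were produced.

## Dwell-time analysis

Durations above the deadtime t_d follow the left-truncated mixture

    f(t) = sum_i a_i k_i exp(-k_i t) / sum_j a_j exp(-k_j t_d),

parameterized directly by the deadtime-corrected fractions a_i, so the
corrected/observed amplitude round trip (`A_i = a_i e^{-k_i t_d} / Z`) is
exact by construction.  Fits maximize the weighted log-likelihood with each
molecule contributing equally by default (per-event weighting available;
the bootstrap resamples molecules, not events, to respect the weighting
unit).  Optimization is multi-start (quantile-anchored starts at 1, 10 and
0.1 times the reciprocal median residual life plus five random log-uniform
starts), L-BFGS-B in log-rate/logit-amplitude coordinates, rates bounded
to [1e-3, 1e6] s^-1 and additionally capped at 5/deadtime — components much
faster than the truncation boundary are unidentifiable and, unconstrained,
occasionally absorb the few shortest events as a spurious ultra-fast
phase; the single-component fit is the closed form
`1 / (weighted mean - t_d)`.  Model order (1-3 components) is chosen
greedily by the nested log-likelihood-ratio test against chi-squared with
2 df per added component at p < 0.05.  The chi-squared reference is
conservative when an amplitude sits on its boundary; the type-I simulation
in the acceptance suite is the guard (measured acceptance of a spurious
component is well below the nominal 5%).  Fits require at least 10 events
per free parameter.

## Ensemble averaging and stroke quantification

Events are aligned at their detected binding times and averaged forward;
each event's displacement beyond its extension point — the displacement at
sigma_t before its detected end — is held constant, and each molecule
contributes equally.  The held displacement is estimated as the mean of the
100 us block ending at the extension point: freezing a single sample would
propagate that sample's noise (and its correlation with the detected end)
into every later time point of the average.  Displacement is the leading-trap position minus its
value at the detected binding time, with the stroke direction positive.
Reading that value from the single sample at the detected start couples an
error of (unbound speed) x (start-time error) — tens of nm — into every
event, which at desk-scale event counts buries the stroke; the default
estimator instead takes the extremal 48 us block mean around the detected
start (minimum for hindering events, whose approach comes from above and
stops at the post-stretch minimum; maximum for assisting).  Its small
constant offset is common to all events and cancels in the within-curve
quantification.  The raw-sample reference remains available
(`reference="sample"`).

Quantification follows the fixed recipe: zero is the minimum within the
first 1 ms after binding; t_init is the argmax of the raw average within
1.2 ms after that minimum (5 ms at 1.5 pN, where smoothing is heaviest);
the initial displacement averages the 200 us window centered on t_init
(the same window serves as the dip reference); the dip is the minimum of a
1 ms moving average (edge-truncated windows) between t_init and 15 ms; the
total displacement is the mean of the last 200 us.  The stroke rate comes
from a least-squares fit of `1 - exp(-k (t - t_min))` to the
min-max-normalized average between the minimum and t_init — amplitude
fixed at 1 and time origin anchored at the minimum, the simplest choice
consistent with the stated procedure (the anchor is configurable).  Because
the normalization uses the windowed maximum, rates with k * t_init below
about 3 are biased upward by the unsaturated amplitude; at the observed
stroke rates (>= 3000 s^-1 at >= 3 pN) the bias is under 1%.

A measured consequence of the mechanical model: the recovered ensemble
stroke amplitude is the 6 nm lever-arm step minus the series-elastic
stretch F/kappa (2 pN/nm), i.e. ~4.5 nm at 3 pN — the same compliance
effect that makes the measured step decrease linearly with load.

## Model comparison

`predict_ensemble` simulates interactions under a scheme with the same
mechanics and noise as the trace generator (3000 interactions, 25 ms
duration cutoff by default), builds per-event displacement traces
(constant-slope approach, exponential stretch, per-state positions with
0.1 nm jitter), and averages them with the same extension/weighting routine
used for data.  Each interaction uses a child generator seeded by
(seed, index), and the two phosphate levels of a comparison share those
seeds: paths are sample-for-sample identical until their first
Pi-dependent branch, so condition deltas are a paired comparison driven
only by genuinely phosphate-affected events (a large variance reduction at
fixed n).  The stroke-rate confidence interval in comparisons is an
event-level bootstrap (40 resamples, 95% percentile), because the curve-fit
covariance misses the variability of the argmax/normalization steps.

`compare_orderings` reports, per scheme and force, the 10-minus-0 mM deltas
of dip amplitude, dip timing, total displacement and stroke rate, and flags
whether the scheme reproduces the experimental directionality (phosphate
enlarges and delays the dip, reduces the total displacement, leaves the
stroke rate unchanged within CI).  The stroke-first preset does; the
phosphate-first preset instead slows the stroke beyond CI — the
discriminating counterfactual.

## Problem sizes and determinism

Defaults reproduce the study conditions: 250 kHz sampling, 1.5-4.5 pN,
200 nm excursion, 2 ms pauses, published deadtimes, 3000 interactions and
the 25 ms cutoff for model predictions, 500 bootstrap rounds with 68%/90%
intervals for dwell fits.  The test suite exercises the chain at
desk scale: end-to-end recovery uses 8 molecules per force at ~8 attachments/s
(135 s per molecule at 3 pN, 270 s at 4.5 pN where the deadtime truncation
leaves the fewest fast events; several hundred to ~1500 analyzed events
per condition, matching the per-condition event counts of the experimental
datasets) at 3 and 4.5 pN, where time resolution is informative.  Every stochastic component
takes an explicit seed; a fixed seed reproduces traces, fits, and
predicted ensembles bit-for-bit.

## Known limitations

- The noise model is spectral shorthand (white + one OU scale); absolute
  deadtimes land at 0.5-0.95x the published values and binding-time
  uncertainties at ~70-400 us rather than the published 60-500 us span.
- The preset rate tables beyond the printed anchors are directional
  calibrations, not fitted constants.
- Dwell-duration measurement error near the deadtime slightly biases the
  fastest fitted rate (a few percent at 4.5 pN, where 1/k_f approaches the
  boundary-time uncertainty).
- Assisting-load boundary trims are not applied (the assisting approach has
  no extremum at binding); assisting ensembles therefore carry larger
  alignment noise.
- No per-event step detection, no bead-covariance stiffness channel, no
  dual-head kinetics, no thermodynamic bookkeeping.
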