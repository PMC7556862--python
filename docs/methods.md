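# Methods

`votcortex` models and analyzes how a temporal speech cue — voice-onset time
(VOT), the interval between a stop consonant's release burst and the onset of
voicing — can be represented by a *spatial/amplitude* neural code in human
auditory cortex. The package has two halves: a deterministic five-node
leaky-integrator network that turns burst/voicing timing into response
amplitudes, and an ECoG-style analysis pipeline (preprocessing, electrode
selection, encoding statistics, corruption-based decoding, latency and
evoked-potential bootstraps, psychometric fitting) driven by seeded
synthetic-data generators so that every stage runs and is testable offline.

## The gap/coincidence network

Five localist units — burst detector, voicing detector, inhibitory unit, gap
detector, coincidence detector — evolve on a discrete clock (1 cycle = 10 ms,
100 cycles per simulation). Each cycle a unit first decays toward its resting
level ρ by its decay rate λ without overshooting, then adds clamped external
input plus Σⱼ wⱼᵢ·aⱼ(t−1) over presynaptic units whose previous-cycle
activation reached their propagation threshold θⱼ; the sum is clipped once to
[m, M]. Output is the activation where it is at/above θ, drawn at ρ otherwise.

The circuit motifs are classical:

* **Gap detection (slow IPSP).** The burst excites the gap detector directly
  (fast suprathreshold response, since θ_gap < w_burst→gap) and, one synapse
  later, inhibits it through the inhibitory unit. Voicing arriving while the
  inhibition is still decaying cannot drive a second suprathreshold response;
  as the inhibition wears off (λ_gap per cycle), later voicing drives
  responses that grow with the gap. Result: uniform weak responses to 0–20 ms
  VOTs, graded stronger responses to 30–50 ms, onset latency locked to the
  burst.
* **Coincidence detection.** The burst alone is subthreshold at the
  coincidence detector (θ_coinc > w_burst→coinc) but transiently raises its
  potential; voicing arriving before the boost decays sums with it. Result:
  strongest response at 0 ms, graded decrease to 20 ms, identical responses
  for 30–50 ms (the boost is gone by 3 cycles, λ_coinc·3 ≥ w_burst→coinc),
  onset latency locked to voicing.

### Default parameters

The shipped defaults (`data/default_network.json`) are hand-calibrated so the
four stated sensitivity constraints hold and both units place the category
boundary between 20 and 30 ms:

| parameter | fast units (burst, voicing, inhib) | gap | coinc |
|---|---|---|---|
| resting ρ / bounds [m, M] | 0 / [−5, 5] | 0 / [−5, 5] | 0 / [−5, 5] |
| decay λ (per cycle) | 2.0 | 0.2 | 0.3 |
| threshold θ | 0.5 | 0.95 | 1.2 |

Weights: burst→{inhib, gap, coinc} = 1.0; voicing→{gap, coinc} = 1.9;
inhib→gap = −2.2. Inputs clamp 1.0 onto the burst detector at cycle 2 and 1.0
onto the voicing detector at cycle 3 + VOT/10.

The one-cycle base lag of the voicing clamp is structural, not cosmetic: the
inhibitory path burst→inhib→gap is three synapses against two for
voicing→gap, so for a 0 ms VOT the slow IPSP reaches the gap detector on the
same cycle as the voicing EPSP only if voicing detection trails the transient
burst by one cycle. Physically this is the finite rise time of the voicing
amplitude envelope relative to the 2 ms burst. Without the lag a 0 ms VOT
would drive the *largest* gap response, inverting the circuit's purpose.

The model also predicts VOT-dependent *peak* latency in both integrator
units; `peak_output_cycle` reports it, and no analysis or test asserts
anything about it.

## Synthetic data

The generators define the study conditions: 7 participants (4 with behavioral
responses), six VOT steps 0–50 ms, 50 trials per step per participant, epochs
−500..+1000 ms at 400 Hz, and per participant 5 voiced-selective (V+),
3 voiceless-selective (V−), 2 VOT-insensitive and 2 non-responsive
electrodes (mirroring the roughly 2:1 prevalence of V+ over V− sites).

**Evoked kernel.** Each responsive electrode adds to AR(1) Gaussian baseline
noise (SD 1 z-unit, coefficient 0.9 at 400 Hz) an evoked response with a
half-raised-cosine rise (55 ms), a sustained plateau (100 ms), and an
exponential fall (τ = 150 ms), peaking at onset + 55 ms with exactly the
class's tuned amplitude. Three features of this shape matter and were chosen
for internal consistency of the ground truth, not for convenience:

1. *Common onset transient.* The amplitude tuning blends in by raised-cosine
   ramp over the last 15 ms of the rise; below that the trace is identical
   across VOTs. Threshold-crossing onset latencies (defined as first crossing
   of 50% of the grand-mean peak) therefore do not spuriously track amplitude
   tuning — without this, V− electrodes would show a strong artifactual
   latency–VOT association that burst-locked cortical sites do not show.
2. *Sustained plateau.* Because the peak-amplitude statistic is read at one
   fixed sample (the grand-mean argmax), a purely transient kernel makes the
   value at that sample depend on each condition's onset latency, converting
   the V+ latency code into a spurious within-nonpreferred amplitude code.
   The 100 ms plateau decouples the two, as sustained STG responses do.
3. *Peak at 140 ms.* The tuning ramp completes before the 150–250 ms peak
   analysis window, so inside the window the trace is proportional to the
   tuned amplitude. A generator whose "amplitude-coded" variant leaks timing
   structure into the analysis window would contradict its own ground truth.

Tuning curves (z-units): V+ (4.5, 3.8, 3.1, 1.8, 1.8, 1.8) over 0→50 ms with
onset slope 1 ms/ms (voicing-locked); V− the mirror image with zero slope
(burst-locked); non-selective flat 2.8. Trial-to-trial multiplicative gain
jitter SD 0.1. `amplitude_coded_config()` zeroes the onset slopes and the
blend (strict proportional scaling); `latency_coded_config()` uses flat
amplitudes with slope 1.

**Behavior.** Responses are Bernoulli with
P(/pa/) = logistic(β₀ + u_p + β_VOT·VOT), β₀ = −4.2, β_VOT = 0.2 (boundary
21 ms), participant offsets u_p ~ N(0, 0.5²); reaction times are lognormal
with 2% omissions and 1% gross outliers to exercise the exclusion rules.

**Evoked LFP.** Raw-voltage epochs are AR(1) noise (coefficient 0.97, SD
30 µV) plus three Gaussian-windowed deflections — P_α (+40 µV at 90 ms), N_α
(−60 µV at 130 ms), P_β (+50 µV at 200 ms) — whose latencies and amplitudes
may depend linearly on VOT (default: independent).

**Raw mode.** A continuous broadband record (1600 Hz) with pink-ish noise, a
shared 60 Hz line component, and a 70–150 Hz narrowband carrier whose
envelope carries the same evoked structure, used to exercise the whole
preprocessing chain.

What the generators do *not* emulate: epileptiform artifacts, electrode
geometry and spatial correlation, non-stationary arousal effects, shared
(global) trial-to-trial fluctuations across electrodes, and acoustic
waveforms. Passing tests therefore certify the pipeline's statistical logic
on data with the assumed structure, not its behavior on every pathology of
clinical recordings.

## Signal processing

Zero-phase second-order IIR notches at 60/120/180 Hz; common-average
reference over all good electrodes (or 16-electrode rows); high gamma as the
mean analytic amplitude of eight Gaussian frequency-domain band-passes with
centers geometrically spaced over 70–150 Hz and bandwidth proportional to
center frequency (σ_f = f_c/8 — the cited scheme's exact band edges are not
restated in the literature we follow, so this parameterization is
approximate); polyphase resampling to 400 Hz; epoching −500..+1000 ms with
trials overlapping excluded segments dropped for all channels; z-scoring per
electrode by the mean/SD of the −500..−200 ms baseline pooled over trials
(pooled rather than per-trial, for stability); then a 50 ms centered boxcar
per trial (truncated at epoch edges, which lie outside all analysis windows).

## Selection and encoding statistics

Speech-responsive: grand-mean HG over 100–300 ms above 1 baseline SD. Peak:
grand-mean argmax in 0–500 ms, earliest on ties. VOT-sensitive: Spearman ρ
between per-trial peak amplitude and VOT with midrank ties and the
t-approximation p-value (exact permutation available for n ≤ 8), p < 0.05
uncorrected, V+ for ρ < 0 and V− for ρ > 0. Between-category
discriminability is the tie-corrected Mann-Whitney z without continuity
correction (so the worked example [1,2,3] vs [4,5,6] gives z = −1.964);
within-category encoding uses t = ρ√(n−2)/√(1−ρ²) with a ±∞ sentinel at
|ρ| = 1; group tests are Wilcoxon signed-rank, exact for n ≤ 25 (enumeration
for tied samples up to n = 12), normal-approximate with tie correction
beyond. For pooled preferred/non-preferred tests the V+ electrodes'
t-statistics are multiplied by −1 so positive always means stronger toward
the preferred endpoint.

## Decoding

Features are all speech-responsive electrodes × the 150–250 ms window,
reduced by PCA to 90% cumulative variance (fit once on all trials, matching
the described order of operations; a strictly fold-internal PCA is available
via `pca_within_folds=True`), classified by LDA with pooled covariance and a
small shrinkage ridge under leave-one-out cross-validation. Timing corruption
draws one uniform integer jitter in [−20, 20] samples (±50 ms) per trial,
applied to all electrodes; edge-exposed samples repeat the epoch edge and
never reach the analysis window. Amplitude corruption divides each trial's
full series by the mean peak amplitude of its voicing category at each
electrode's peak; in the doubly corrupted condition normalization precedes
jittering.

Two properties of this design are worth stating plainly because they shape
what "chance" means in the corrupted conditions:

* The amplitude corruption equalizes category *means* (exactly, at every
  timepoint when trial variability is proportional to the response; at the
  peak sample in general). It does not equalize category *variances*: with
  additive baseline noise, dividing by different category means leaves the
  noise heteroscedastic, and a high-dimensional LDA can convert that into a
  small accuracy lift (the class with tighter scaled noise hugs its sample
  mean). With balanced V+/V− populations the asymmetry cancels; at the 2:1
  imbalance of the default conditions a residue of ~2–3 accuracy points can
  remain, within the per-participant binomial chance band. The acceptance
  check therefore requires the −A group means to lie in that band (±5.7
  points for 300 trials) and to sit > 30 points below the +A conditions.
* The *default* synthetic conditions plant both an amplitude code and (at V+
  electrodes) a latency code, as real voiced-selective populations carry
  both. In a pipeline report on default data the −A+T condition therefore
  stays well above chance — correctly, since timing information genuinely
  remains. The clean dissociation is evaluated on the dedicated
  `amplitude_coded_config` / `latency_coded_config` conditions.
* A uniform ±50 ms jitter corrupts but cannot fully erase a deterministic
  0–50 ms latency code, so on strongly latency-coded data the −T conditions
  can stay above chance; the dissociation is expressed in the paired
  contrasts (removing timing hurts, removing amplitude does not), which is
  what the latency-coded acceptance test asserts. Near-ceiling accuracies
  also make the n = 7 sign test sensitive to arbitrarily small consistent
  differences, so "comparable" conditions are defined as paired signed-rank
  p ≥ 0.05 *or* a mean difference ≤ 2 accuracy points.

## Temporal dynamics

Onset latency is the first post-onset sample whose per-VOT mean exceeds 50%
of the grand-mean peak. Bootstraps (1000 resamples, stratified within VOT)
propagate this to a distribution of Spearman ρ(latency, VOT) per electrode;
resamples with an undefined latency for any VOT — or with all six latencies
tied, where the rank correlation is undefined — are dropped, and an electrode
is excluded when fewer than half its resamples survive.

AEP peaks are sought sequentially: P_α = max in 0–150 ms, N_α = min in
[max(75, t(P_α)), 200] ms, P_β = max in [max(150, t(N_α)), 250] ms; an
extremum on either edge of its effective window is invalid and invalidates
the later peaks of that trace. Bootstrapped Pearson correlations of VOT with
each peak's latency and amplitude are summarized by the 95% highest-density
interval (shortest contiguous interval over the sorted resampled values);
a statistic is significant when its HDI excludes zero. No multiple-comparison
correction is applied to the six statistics per electrode. Pearson is used
for the AEP statistics and Spearman for the high-gamma latency analysis,
deliberately keeping the two conventions distinct.

## Behavior

Omissions and reaction times more than 3 participant-SDs from the
participant mean are excluded; participants with fewer than 2 responded
trials are dropped and flagged. The psychometric model is a logistic
regression with a shared VOT slope (VOT continuous in ms) and
per-participant intercept offsets carrying a Gaussian penalty of unit
inverse variance — a penalized-likelihood stand-in for random intercepts;
an unpenalized fixed-intercept mode exists and agrees with the penalized
fit to within ~0.02 in slope at the default data sizes. A minute (1e−8)
ridge on the slope and intercept stabilizes the optimizer under separation;
slopes steeper than 1.5/ms (a transition narrower than ~3 ms) are flagged as
quasi-separation. The category boundary is χ = −β₀/β_VOT, per participant
with the adjusted intercept.

## Numerical and design choices

* All randomness flows through `numpy` Generators seeded from explicit
  integers; bootstraps, jitters and generators are bit-reproducible, and the
  pipeline report contains no timestamps so identical configurations give
  byte-identical reports.
* Peak/argmax ties resolve to the earliest sample throughout.
* The boxcar uses a truncated centered window at the edges.
* The percent-of-max curve is (x − min) / max(x − min); a constant curve is
  an error rather than 0/0.
* The HDI of n sorted values takes the shortest window of ⌈0.95·n⌉
  consecutive values.
* Problem sizes in tests and in `scripts/acceptance.py` are scaled-down
  study conditions chosen as the package's own defaults: 7 participants × 50
  trials/VOT for decoding and recovery, 280 null electrodes for the
  false-positive calibration, 400–1000 bootstrap resamples, 600 behavioral
  trials × 4 participants for psychometric recovery.

## Known limitations

* The network parameters are a calibrated default satisfying the published
  constraints, not fitted values; any parameter file with the same JSON
  schema can be dropped in.
* The penalized psychometric estimator differs from an integral-based mixed
  model in the third decimal of the slope at realistic sizes.
* Threshold-crossing onset latency retains a weak sensitivity to amplitude
  tuning whenever noise pushes the crossing into the tuning ramp; V−
  per-electrode bootstrap means scatter within roughly ±0.3 around zero at
  default noise, and with tens of electrodes this small bias can reach
  nominal significance in the V− group test even though the V+/V− contrast
  remains an order of magnitude larger.
* Decoding "chance" in corrupted conditions is a band, not a point, for the
  variance-structure reasons above.
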