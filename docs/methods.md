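# Methods

`tvrpipe` analyzes two-photon calcium-imaging sessions recorded while a
head-fixed mouse runs on a treadmill inside a tactile virtual reality: a
textured wall moves into whisker reach after the animal has run a set
distance and rotates either at the run speed (closed loop), at an
independent speed (open loop), or stays out of reach while the motors run
(no-touch sound control). The raw data for such experiments are rarely
deposited, so the package pairs the analysis chain with a generative model
of the same experiment; every analysis stage is validated by recovering
generative ground truth.

## Synthetic sessions

**Trial structure.** Sessions are composed of 20-s trials with 3–5-s
inter-trial intervals (defaults; both configurable). Behavior runs
continuously across trials.

**Locomotion.** Rest and run alternate as a semi-Markov process with
exponential bout durations. With `run_bout_rate` b bouts/min of mean
duration d s, running occupancy has the closed form b·d/60; the defaults
(3 bouts/min, 10 s) give 50%, matching animals that spend about half their
time running. Within a bout, speed ramps over 0.4 s to a per-bout target
drawn from N(10, 3²) cm/s (floored at 2 cm/s) with slow ±10% modulation.
No published distribution of bout statistics exists for this paradigm;
these are one-time choices of plausible values, not claims about real
mice.

**Whisking.** Running is always accompanied by whisking: every run bout is
dilated by 1 s on each side and added to the whisking state, so
running-without-whisking has zero generative occupancy (and <1% after
pipeline smoothing). Rest gaps additionally contain whisk-only bouts with
probability `rest_whisk_prob` (default 0.5, mean 3 s). The whisker angle
is band-limited 5–15-Hz noise scaled to an 8° standard deviation during
whisking and 0.2° jitter otherwise — only the sliding-window std of the
angle is consumed downstream, so no biomechanical realism is attempted.

**Touch and perturbations.** In closed loop the stage-in time is the first
moment the within-trial cumulative run distance reaches `touch_distance`
(5–50 cm); contact starts 0.2 s later (stage travel) and lasts to trial
end, with texture speed equal to run speed. In open loop the stage-in time
is drawn uniformly within the trial so touches happen during running and
resting alike, and texture speed comes from an independent bout process.
No-touch sessions move the stage and rotate the texture exactly as closed
loop but never make contact, providing sound-control events. Perturbations
halt the texture for 2 s once per contact period at a uniformly random
admissible time; they are generated in perturbed-closed-loop and open-loop
sessions.

**Fluorescence forward model.** Each neuron's rate is
baseline + run term + touch term + run×touch interaction
(+ optional perturbation term); the run term is either a state gain or the
piecewise-Gaussian speed-tuning curve below. Negative sums are clipped at
zero with a warning (suppressed cells need negative gains). Spikes are
Poisson per 100-ms frame; dF/F is their linear convolution with a
single-action-potential kernel of fractional amplitude A (drawn from
8–11%) and decay constant tau (0.3–0.4 s), plus Gaussian noise (default
sd 0.02). The kernel is integrated over each frame bin, so its discrete
sum is exactly A·tau/dt and a constant rate r yields steady-state
dF/F = r·A·tau with no discretization bias; this identity is what the
forward/inverse consistency check exercises. Raw fluorescence is
F = f0·(1 + dF/F) + background.

What the generator does **not** emulate: photon shot noise and neuropil
contamination, motion artifacts, indicator saturation and nonlinearity,
bursting statistics, multi-whisker kinematics, or any correlation
structure across neurons. Passing recovery tests therefore demonstrates
the correctness of the analysis chain under the model's assumptions, not
robustness to the full noise structure of real recordings.

## Preprocessing

Background (a per-session scalar; the generator's value for synthetic
data, the trace's 1st percentile otherwise) is subtracted, the trace is
smoothed with a 51-frame first-order Savitzky–Golay filter, and the
baseline F0 is the 1st percentile of the smoothed trace; dF/F =
(F − F0)/F0. Baseline noise σ is the 1st percentile over all stride-1 5-s
windows of the within-window SD; SNR is the 95th dF/F percentile over σ.
The 51-point window is interpreted in frames (5.1 s at 10 Hz). Edge
handling uses polynomial-fit interpolation rather than padding so the
percentile is not contaminated by edge artifacts. A steady-state dF/F
maps to a firing-rate change as rate = dF/F / (A·tau); over the kernel
ranges a 50% dF/F spans 11–21 Hz.

Slice-trace utilities: photobleaching is removed by fitting
a·exp(−rt) + c to all samples outside a −0.24/+1.44-s window around the
transient peak and subtracting only the decaying component; if a constant
explains the kept samples within 1% of the exponential's SSE the trace is
declared bleach-free (the decomposition is otherwise unidentified). Decay
constants come from single-exponential least squares from the peak onward.

## Behavioral segmentation

Whisking: the 51-point sliding SD of the whisker angle is computed at the
native 200-Hz rate (a 0.255-s window spanning the 5–15-Hz whisking band),
downsampled to 10 Hz and thresholded at >2.5°. Computing the SD after
downsampling to 10 Hz would destroy any oscillation at or above the 5-Hz
Nyquist limit, so the native-rate order is the only physically meaningful
one. The same windowed SD is the "whisking envelope" used by the encoding
model. Running: the 40-Hz encoder trace is smoothed with a 1-s-FWHM
Gaussian, downsampled to 10 Hz, smoothed with a 1.1-s first-order
Savitzky–Golay filter, and thresholded at |speed| > 0.8 cm/s.

Onsets require ≥400 ms off then ≥400 ms on. Whisking-onset segments end
at whisking offset or running onset, whichever comes first; running
segments end at running offset. Touch onsets are stage-motion starts that
are followed by contact within 2 s; contactless stage motions are kept
separately as sound-control events. Touch events are split by the mean
smoothed speed in a −1..+4-s window: >2 cm/s during running, <1 cm/s
during resting, the band between excluded from both. Perturbation
eligibility uses the same window and the same >2 cm/s rule (the resting
subset, <1 cm/s, is reported for open-loop analyses); the window
convention is shared with the touch split since no separate one is
defined for perturbations.

## Event-aligned responses

Aligned segments run from 2 s before onset to each event's truncation
time; the per-lag average (over however many events remain at that lag)
is smoothed with a 500-ms first-order Savitzky–Golay filter. Whisking,
running and touch modulation are max(post) − mean(pre); perturbation
modulation P is mean(+0.3..+2 s) − mean(−1..−0.3 s). Responsiveness is
modulation > 2σ (perturbation two-sided at ±2σ). Touch metrics subtract
the pre-touch mean (−1..−0.3 s) and take E as the peak in 0.3–1.3 s and L
as the mean in 2–3 s; percent suppression is 100·(E − L)/E for E > 0.
The E-as-peak / L-as-mean convention is a design choice (the defining
equation is not printed in the source material); suppression is invariant
to constant offsets by construction. The modulation index between two
condition means is (a − b)/(a + b), undefined (and excluded from
population statistics) when a + b ≤ 0. The whisking index uses rest
frames only; the running index ignores whisking state. Neurons imaged in
several sessions enter population summaries once, via a seeded random
session — except perturbation summaries, which take each neuron's most
responsive session (an acknowledged overestimate).

## Speed tuning

Frames above 1 cm/s are divided into k = 10 equal-occupancy (quantile)
bins; the stationary bin is kept separate and excluded from fits and from
the one-way ANOVA gate (p < 1e-3) on per-frame dF/F across bins. Tuning
curves are y(s) = y_max·exp(−(s − s_max)²/σ_s) with σ_s = σ− below s_max
and σ+ above (σ_s enters linearly, carrying units (cm/s)², as printed in
the source formula). Three constrained fits — increasing (s_max above the
session's maximum speed), decreasing (s_max ≤ 1 cm/s), band-pass (s_max
free) — use bounded multi-start least squares (5 seeded starts, ftol/xtol
1e-8; a non-converging regime scores zero). Frames are split 80/20
stratified by bin (seeded); per-bin training means are fitted and per-bin
held-out means score the explained variance. Band-pass wins only when its
EV beats both monotone fits and 1 < s_max < max speed; any
classification requires EV ≥ 0.30, else the neuron is unclassified.

## Functional classification

Open-loop sessions only. Per-frame conditions are the running bit × touch
flag; sessions missing any of the four conditions are excluded. The dF/F
trace (500-ms Savitzky–Golay smoothed) is bootstrap-resampled 100× at the
trial level (trials drawn with replacement; frames pooled per condition
with trial multiplicities as weights); the mean and SD over replicates
give each condition's mean and bootstrap SD. A cell is assigned to the
condition with the largest mean (rest / run / touch / integrative). When
the margin to the runner-up is below the top condition's bootstrap SD the
cell is demoted — but only toward the *less specific* of the two
conditions (component counts: baseline 0, run or touch alone 1, run+touch
2). A literal "always take the runner-up" rule would promote
single-component cells to integrative on statistical ties, the exact
opposite of the rule's conservative intent, and caps ground-truth category
recovery near 73%; the directional rule recovers ≥90%. Exact ties break
toward the less specific condition. Population statistics draw 11
sessions 10 times (seeded, redrawn if a layer goes empty), compute
per-category percentages per layer, and compare layers with a two-sample
t-test per category.

## Mutual information

Variables are discretized into uniform bins with
k = range/(2.5·iqr·n^(−1/3)), where n is the samples per trial; k is
computed per trial and the session-wide median used. (With ~200 frames
per trial this yields k ≈ 10–15; the per-trial n matters, since
whole-session n would inflate k and with it the plug-in bias
(k−1)²/(2N·ln2).) MI is the plug-in Shannon estimate in bits over the
joint histogram; no bias correction is applied. The printed source
formula omits the logarithm — treated as a typographical omission. The
calcium delay is scanned over ±1000 ms in 100-ms (one-frame) steps; the
value at +200 ms delay, where calcium-driven signals peak, feeds all
downstream comparisons, including the per-neuron ΔI between touch and
no-touch frames (computed with shared session-wide bin edges; either
condition under 10% of frames makes the result missing, mirroring the
session-inclusion rule of ≥10% time running).

## Encoding model

A random forest (32 trees, minimum leaf size 10, seeded) predicts dF/F on
whisker-contact frames from run speed, texture speed, and the whisking
envelope, each at seven shifts (±300 ms, p = 3), i.e. 21 columns; shifted
columns are built on the full timeline (edge-replicated) before masking.
Five seeded repeats hold out 20% of frames as non-overlapping 2-s
contiguous chunks drawn uniformly without replacement. Q_i = 1 −
SSE/SST with SST around the training mean, clipped at zero; Q̄ is their
mean. Shuffle importance permutes a predictor's seven columns together
with one global permutation of the test rows per repeat (preserving the
marginal, destroying the temporal relation): ΔQ = Q̄ − Q̄_shuffled.

## Orchestration

Sessions live on disk as plain-text CSV/JSON directories; reads are
validated for required files, declared rates, and stream alignment, and
round-trip losslessly. NaN frames (excluded periods) propagate through
every metric via NaN-aware reductions. Every stochastic stage derives its
seed deterministically from (global seed, stage name, session id), so a
cohort report is byte-identical across reruns. A failing session is
isolated and reported without stopping the cohort.

## Validation problem sizes

The recovery suite (also run by `scripts/acceptance.py`) uses: 1,000
random 6-s binary sequences for the onset oracle; n = 12,000 samples ×
20 seeds for the MI independence check; 200 mixed-category neurons in one
20-trial open-loop session for category recovery; 50 band-pass neurons
(6,000 frames) plus 100 noise neurons (2,000 frames) for tuning; 20
driven + 20 noise targets of 1,500 frames for the encoding model; 100
constant-rate neurons for forward-model consistency; 25 + 25
sustained/transient touch neurons in a 25-trial closed-loop session for
suppression; and 100 noise neurons in a 30-trial no-touch session for the
sound-control false-positive rate. These sizes were chosen so each check
is statistically decisive at its tolerance while the whole suite stays
lightweight.

## Known limitations

- The generator's behavioral statistics are plausible but unvalidated
  against real treadmill data; absolute values of population percentages
  depend on them.
- The plug-in MI estimator is biased upward on small conditions; ΔI
  comparisons rely on the bias canceling between conditions of similar
  size.
- Savitzky–Golay and Gaussian smoothing widths shift detected state
  boundaries by up to ~0.8 s; occupancy comparisons must allow for this.
- The bleach-correction exponential is unidentified on traces much
  shorter than its time constant; such traces are returned unchanged.
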