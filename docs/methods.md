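# Methods

## The periphery model

The cochlea is modelled as a bank of linear order-4 gammatone band-pass
filters followed by a memoryless inner-hair-cell stage. For a channel with
centre frequency `cf` the filter's equivalent rectangular bandwidth (ERB) is
set by the species law:

* human: `ERB(f) = f / (12.7 * (f/1000)^0.3)` Hz (derived from
  simultaneous-masking psychophysics);
* ferret: `ERB(f) = f / 8.9047 + 209.6149` Hz (a linear fit to auditory-nerve
  tuning-curve bandwidths).

Ferret ERBs exceed human ERBs at every frequency in the audible range (a
property-tested invariant). The gammatone is realized in the frequency
domain through its exact analytic transfer function
`H(f) = (1 + j(f - cf)/b)^-4` plus the negative-frequency image, with decay
parameter `b = ERB * Γ(4) / (√π Γ(3.5)) ≈ 1.019 * ERB` (the standard
order-4 ERB conversion), normalized to exactly unit gain at `cf`. This is
numerically identical to the canonical time-domain filter, trivially
vectorizes over 500 channels, and is deterministic to the bit. Signals are
zero-padded past the ring-out of the narrowest filter before the FFT so the
circular convolution has no wrap-around.

Transduction follows the filter: half-wave rectification, amplitude
compression to the power 0.3, and a zero-phase FIR low-pass (Kaiser design;
passband 3 kHz, stopband 4 kHz, ≥ 60 dB stopband attenuation, designed with
a 6 dB margin) that models the loss of phase locking to fine structure. The
low-pass ripple can undershoot zero by a vanishing amount, so the output is
clipped at zero to keep the nerve response nonnegative.

Defaults: 500 channels, log-spaced centre frequencies 100 Hz–10 kHz
(covering the stimulus band; the true fibre grid of the comparison this
emulates is not published, so the grid is configurable, including an
ERB-rate spacing), 48 kHz sample rate (comfortably above twice the highest
stimulus component at 10 kHz).

## F0-power metrics and the cross-species comparison

For each channel, a 200 ms steady-state window starting 50 ms after stimulus
onset is analysed (onset transient excluded). The window length is snapped
to a whole number of F0 cycles so F0 falls exactly on a DFT bin. Three
related per-fibre quantities are computed:

* `power` — the raw mean-square response power in the F0 bin;
* `fraction` — that power as a proportion of the channel's total non-DC
  power (rectification plus compression give every channel a large DC
  offset that carries no periodicity information, so DC is excluded);
* `normalized` — `fraction` divided by its maximum across channels.

The species comparison uses a two-sided Wilcoxon rank-sum test on the two
sets of 500 normalized fractions (tie-corrected normal approximation,
positive z when the ferret ranks higher). With the default grid this gives
z ≈ 10.0; the value moves between roughly 9.5 and 11 across reasonable grid
choices because the pooled-rank overlap depends on how many channels sit
below the stimulus band.

The two metrics deliberately coexist because they answer different
questions. The *matched-pair* claim — the ferret response carries more F0
power than the human response at every simulated fibre — holds robustly for
`power` (minimum ferret/human ratio ≈ 3 at the default grid) but **not** for
the max-normalized fraction: a human channel centred midway between two high
harmonics passes essentially only those two components, whose beat is ~100%
modulated at F0, driving its fraction toward 1. Normalizing each species by
its own maximum then lets such channels exceed their ferret counterparts.
The acceptance test for the pairwise claim therefore uses `power`, while the
rank-sum (a pooled, scale-aware comparison) uses the normalized fractions.

Harmonic resolvability is estimated as `round(F0 / ERB(F0))` (round half
away from zero, clamped to ≥ 0); this rounding reproduces the expected 1–8
range for ferrets over 150 Hz–10 kHz where floor or ceiling do not.

## Stimuli

Harmonic complexes contain every harmonic `n*F0` inside the band, all with
equal amplitude and (by default) sine starting phase — the convention that
maximizes envelope modulation; random-phase variants draw each phase
i.i.d. uniform from a stated seed. The waveform RMS realizes the nominal
dB SPL level under a single full-scale-to-Pascal calibration constant
(absolute SPL is unverifiable in the digital domain; all levels are exact
relative levels). The per-component level is `level - 10*log10(n_components)`.
All stimuli get 5 ms raised-cosine ramps (disable with `ramp_s=0`) to avoid
spectral splatter.

Band edges per condition live in an editable packaged table
(`data/probe_bands.yaml`). The ferret standard bands are fixed by the task
design (1–10 kHz for the 500/1000 Hz pair; 0.9–9 kHz for the 150/450 Hz
pair, which preserves matched spectral edges with integer harmonics of both
F0s); the low/high-harmonic probe edges follow the resolvability rule above
and are flagged approximate where the published account gives them only
graphically. Human targets are 180 and 220 Hz with low-harmonic spectral
edges of 360 and 220 Hz respectively, so the edge cue is incongruent with
F0.

The pink-noise masker is synthesized in the frequency domain (PSD ∝ 1/f
inside 0.1–10 kHz, zero outside) and calibrated by measurement: the returned
gain makes the noise level after an order-4 gammatone at the target F0
(ferret ERB, matching the bandwidth data that motivated the masker) equal to
the target's component level minus 5 dB.

## Behavioural analysis

Exclusions run in a fixed order: session-level performance is computed on
error-correction-free standard trials first, then error-correction trials
and all trials of sub-60% sessions are dropped. This is the only order in
which forced-repeat trials can never disqualify a session. Probe scores are
normalized as `Pnorm = (P - 50)/(S - 50)`; `Pnorm` is undefined (raises)
when the standard score is exactly 50%.

The group statistics are two-sided throughout (α = 0.05): one-sample and
paired t-tests, a fixed-effects two-way ANOVA with interaction (Type-I sums
of squares on balanced data; statsmodels OLS under the hood) and Tukey HSD
(statsmodels, cross-checked in tests against SciPy's studentized-range
implementation). Repeated-measures models are intentionally out of scope:
with the small unbalanced animal cohorts such analyses sacrifice subjects,
so subjects are treated as independent measures across reference conditions.

The rank-sum statistic is computed in-house: tie-corrected normal
approximation without continuity correction for large samples, exhaustive
enumeration of rank assignments (exact, tie-aware) whenever the pooled
sample size is at most 12. The exact path is verified byte-identical to a
brute-force oracle; users should be aware that for very small groups the
normal approximation is a poor substitute for the exact p (deviations above
0.2 are possible at n = 2–3 per group), which is precisely why the exact
path exists.

## The synthetic observer

The generator emulates the *statistics* of the task, not its acoustics:
per-session trial counts are truncated-normal (94, 24); each trial is a
probe with probability 0.2, with the four probe classes equally likely;
responses are Bernoulli with the condition's accuracy, mixed with a lapse
rate toward chance and shifted by a side bias; after an incorrect standard
response (ferret task only) the next trial repeats the same F0 class and is
flagged as an error-correction trial — a single repeat per error, itself
eligible to trigger another repeat if wrong. Everything is reproducible
from one seed.

What passing these tests shows: the analysis pipeline recovers known
generative parameters and detects a built-in species × condition
interaction at the task's real trial counts. What it does not show:
anything about real listeners — observer accuracies are parameters, with no
within-session learning, no reaction times, and no link from the simulated
cochlea to the simulated decisions.

## Numerical choices and limitations

* Window snapping: the analysis rejects (rather than silently detunes) an
  F0 that misses the DFT bin grid by more than 0.1%.
* Exact rank-sum enumerations use a 1e-9 tolerance when counting "at least
  as extreme" rank sums, so midrank ties do not flip on float noise.
* Degenerate inputs raise: silence in dB SPL conversions, zero-variance
  t-tests, empty ANOVA cells, sessions with no standard trials.
* The model is linear and deterministic: no stochastic spiking, adaptation,
  middle-ear filtering, or suppression. Ferret bandwidths from pure-tone
  tuning curves likely *underestimate* effective bandwidths (no lateral
  suppression), so the simulated species difference is conservative.
* Scale of the shipped analyses: the cross-species simulation runs 500
  channels per species over a 0.3 s stimulus at 48 kHz (a few seconds of
  compute); synthetic-observer validations use ~10^5 trials, enough for
  binomial confidence intervals a few tenths of a percentage point wide.
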