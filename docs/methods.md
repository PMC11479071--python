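# Methods

This note records the models, parameter choices and numerical decisions
behind `pulsebeam`, and what the synthetic benchmarks do and do not show
about real radar data.

## Signal model

An IR-UWB radar frame is a range profile of complex baseband samples; bin
*k* maps to range `range_start + k·Δr` with Δr = c/(2·23.328 GHz) ≈
6.43 mm, and frames arrive at 250 Hz (4 ms slow-time resolution).  A
breathing, beating person at range *R*₀ contributes to nearby bins a
return

&nbsp;&nbsp;&nbsp;&nbsp;*s*ₖ(*t*) = env(*k*Δr − *R*₀ − d(*t*)) · exp( j·4π(*R*₀ + d(*t*))/λ ),

with λ = 0.04 m (7.5 GHz centre frequency) and chest displacement

&nbsp;&nbsp;&nbsp;&nbsp;d(*t*) = A_resp·sin(2π f_resp t) + Σᵢ A_heart·g(t − bᵢ) + movement(t),

where g is a Gaussian pulse (SD 50 ms) at each beat time bᵢ.  A heartbeat
is modelled as a *pulse*, not a sinusoid at the heart rate, because the
peak detector's premise is a sharp slow-time maximum per beat.  The
displacement amplitudes — A_resp = 4 mm, A_heart = 0.3 mm — are
physiological textbook values (the premise that respiration dominates is
asserted as a parameter invariant).  Static clutter per bin, a strong
static direct-path return in bin 0, complex white noise at a configurable
SNR (default 35 dB, relative to target-bin signal power), and a
frame-common phase-jitter random walk (step SD 0.01 rad) complete the
scene.  All draws come from per-component streams spawned from one seed,
so e.g. a jitter-free re-render keeps identical noise — this is what makes
the phase-compensation oracle test exact.

Beat times are generated by cumulating RR intervals

&nbsp;&nbsp;&nbsp;&nbsp;RRᵢ = μ + a_LF·sin(2π·0.10·tᵢ) + a_HF·sin(2π·0.30·tᵢ) + εᵢ,

with the white-noise SD chosen so the total SD matches the requested
value (a sampled sinusoid of amplitude a contributes a²/2 to the
variance).  Defaults (μ = 828 ms, total SD 37 ms, a_LF = 25 ms,
a_HF = 30 ms) mirror a resting adult control population and give an LF/HF
power ratio near 0.7.

Movement bursts are random target offsets in ±amp redrawn every frame.  A
millimetre-scale shift is many carrier wavelengths of two-way path, so
each redraw decorrelates the return completely; this deliberately
overstates what a *point* target would do, compensating for the fact that
real torso motion spreads across many range bins which the single-point
model does not capture.

## Pipeline decisions

**Phase compensation.** Bin 0 (the direct transmitter–receiver path)
should have constant phase; any phase it shows is frame-common error and
is rotated out of every bin of that frame.  The operation is an exact
inverse of the injected jitter — the tests assert < 1e−9 rad residual
(measured ~5e−16).

**Movement statistic before band-pass.** The per-second score uses the
compensated but unfiltered cube, so gross motion is not filtered away.
The threshold is α (default 5) times the trimmed mean (top 10% dropped) of
the whole window's scores: a cell-averaging CFAR with the evaluation as
the reference window, giving one fixed threshold per evaluation and
per-second decisions.  Trimming keeps the bursts themselves from inflating
the threshold.

**Band-pass cascade.** Linear-phase FIR (Hamming-window design) at the
stated orders: low-pass 5 Hz / order 30, high-pass 0.667 Hz / order 1000.
The high-pass edge is 40 *beats per minute* — heart-band edges quoted in
bpm convert as 40/60 Hz; a literal 40 Hz high-pass would annihilate a
~1 Hz heartbeat.  The designed cascade response is −51.6 dB at the
0.25 Hz respiration fundamental and −0.11 dB at 1.2 Hz.  Centred
convolution removes the group delay so peak timestamps are unbiased; the
first/last half-filter (~2 s) carry edge transients and are excluded from
peak detection, which is why a 60 s evaluation reports a few fewer beats
than truth.

**Vital extraction is arctangent demodulation, not the real part.**  With
A_resp = 4 mm and λ = 4 cm the phase modulation index is 4π·A_resp/λ ≈
1.26 rad.  Taking the real part of the compensated signal is a cosine
demodulator: at that modulation depth it generates a respiration third
harmonic at 0.75 Hz *inside* the heart band larger than the 0.09 rad
heartbeat pulses, and its gain vanishes entirely whenever the target
range is near a multiple of λ/4 (a "null point" — 0.70 m is exactly one).
Arctangent demodulation — subtract the static clutter phasor, take the
unwrapped angle — is linear in displacement at any range and has no
harmonics.  The clutter phasor is estimated per bin by a least-squares
(Kasa) circle fit of the IQ trajectory; a vibrating point target traces an
arc whose centre *is* the clutter.  The classical real-part mode is kept
as `select_mp(..., mode="real")` for comparison.

**Bin selection.**  Every bin near the target observes the *same*
demodulated phase, so a heart-band/noise-band power ratio cannot rank
them — noise inflates the in-band numerator, and post-filter spectra of
noise-dominated phase series concentrate in the pass-band regardless of
content.  Selection therefore uses the geometry: bins whose ring-radius
coefficient of variation is below 0.3 pass a coherence gate (noise blobs
sit near the Rayleigh CV of 0.52), and among them the largest mean ring
radius — the strongest vibrating return — is MP.  The band ratio itself
(periodogram power in 40–130 bpm over the complement above 0.05 Hz) is the
selection statistic of the "real" mode and is exposed as a public
primitive.  In simulated scenes the selected bin lands within ±2 bins of
the true target, including at null ranges where the real-part mode is
blind.

**Peak detection.**  The amplitude-ordered iteration takes the global
maximum, zeroes ±R (R = ⌊fps·60/(2·130)⌋ = 57 frames), and repeats until
no positive sample remains or the candidate limit
⌈duration·130 bpm/60⌉ is reached.  Validation keeps candidates attaining
the maximum of the original signal over their own ±R window: the printed
strict inequality can never hold for a window containing the candidate
itself, so ≥ is used (a `strict=True` mode preserves the literal reading,
which rejects everything).  Ties break toward the lowest index;
termination treats "entirely zero" as "no positive sample", since filtered
signals are signed.  The detector is verified sample-exact against an
independent brute-force reference on hundreds of random signals.

**RR construction and movement exclusion.**  An interval is dropped when
its [start, end] span overlaps any flagged second [s, s+1) with positive
measure; survivors are concatenated without interpolation.  The identical
code path consumes radar peak sets and reference beat-time sequences, so
method comparison is symmetric by construction.

**HRV indices.**  SDNN uses the n−1 denominator (HRV-toolkit convention);
RMSSD is undefined (NaN) below three intervals.  The frequency-domain path
tapers the mean-removed interval series with a Hamming window of its own
length, zero-pads to 2¹⁸, and sums *squared* magnitude over LF
[0.05, 0.15) and HF [0.15, 0.40) Hz — half-open bands, so 0.15 Hz belongs
to HF only; plain-magnitude mode is available for sensitivity checks.  The
beat axis maps to Hz through f_eff = 1000/mean RR with no resampling.

**Agreement statistics.**  ICC(2,1) (two-way random effects, single
measure, absolute agreement) is computed from the Shrout–Fleiss mean
squares with the McGraw–Wong F-based 95% CI (Satterthwaite df); pingouin's
ICC(A,1) serves as an independent oracle in the tests.  The validity
screen's SDNN bounds default to the observed reference range of the input
table (fixed bounds can be supplied).  Limits of agreement use 1.96 × the
n−1 SD of the differences.

**Distress analysis.**  ROC thresholds sit at midpoints between sorted
unique values plus ±∞ (the convention of pROC, whose AUC equals the
normalised Mann–Whitney U — asserted against scikit-learn).  Orientation
is fixed per index (low mean RR/SDNN/RMSSD ⇒ distress, high LF/HF ⇒
distress) rather than auto-selected, which would inflate AUC under the
null.  The top-left operating point minimises (1−sens)² + (1−spec)², ties
broken toward higher sensitivity.  Inference contrasts high distress
(VAS ≥ 7.5) against the pooled controls; the four-bin grouping is kept for
descriptive tables.

## Study-level generator

`generate_study` draws, per evaluation, a latent HRV state from its
group's distribution; the reference reports the latent state, the radar
adds a per-index systematic bias and Gaussian noise
(mean RR: 0.05 ± 2.6 ms; SDNN: 3.0 ± 6.2 ms; RMSSD: 11 ± 21.7 ms; LF/HF:
−0.14 ± 0.24 — magnitudes typical of radar-vs-ECG Bland–Altman spreads).
Group means default to a resting office-worker population with a markedly
lower mean RR (727 vs 829 ms) and SDNN (22 vs 34 ms) in the high-distress
group; between-evaluation SDs (80 / 12 / 20 / 0.25) are plausible
population spreads chosen once.  Under these conditions the 90-vs-12
mean-RR ANOVA is significant in ~98% of replicates and the group ordering
holds essentially always.

## Problem sizes

The test suite and acceptance script run clean-scene recovery at the full
evaluation scale (300 s × 250 fps × 172 bins); unit and property tests use
one-minute scenes, 100-replicate study simulations, and 200-signal
detector-oracle sweeps.  The acceptance script finishes in well under a
minute on one core.

## What the benchmarks show — and what they do not

Passing recovery tests show the chain is *correct*: with the stated
physics, the stated algorithms return the generating truth (mean RR within
a fraction of the 4 ms frame quantisation, SDNN within a few percent, RR
sequences correlating > 0.99).  They do not certify field performance:

* the simulator is a single point target with a Gaussian range envelope —
  no multipath, antenna pattern, harmonics of real chest motion, or
  multiple scatterers;
* the thresholdless peak detector degrades sharply once post-filter noise
  approaches the heartbeat pulse amplitude (below roughly 30 dB scene SNR,
  positive noise excursions between beats become validated peaks and SDNN
  inflates long before mean RR moves) — an inherent property of the
  algorithm, documented rather than patched; an optional amplitude floor
  would change the algorithm's identity;
* real radar-vs-ECG disagreement has structure (posture, range migration,
  contact-sensor artefacts) that the additive-Gaussian study generator
  only caricatures;
* repeated evaluations of the same subject are drawn independently; no
  within-subject correlation is modelled.

## Degenerate inputs and tie-breaks

Zero-amplitude reference samples abort compensation with the frame index;
all-equal movement scores with α ≤ 1 warn and flag nothing; a zero series
has band ratio 0, and a zero noise band with nonzero signal returns +∞
with a warning; circle fits of constant trajectories fall back to the
sample mean; equal-amplitude peak candidates and equal band ratios resolve
toward the lowest index; ROC ties on the top-left distance resolve toward
higher sensitivity.
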