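# pulsebeam

Heart-rate variability (HRV) from impulse-radio ultra-wideband (IR-UWB)
radar — a complete processing chain from raw complex fast-time × slow-time
frame matrices to RR intervals, HRV indices, radar-vs-reference agreement
statistics, and VAS-based mental-distress discrimination.

Non-contact vital-sign monitoring uses the phase of a radar return to track
sub-millimetre chest-wall displacement.  The heartbeat rides on a
respiration excursion roughly ten times larger, the frame-common phase
noise of a radar pushed to 250 frames/s corrupts every sample, and any
gross body motion swamps the signal entirely.  This package implements the
processing that copes with all three, and — because no public radar HRV
dataset exists — a physical scene simulator that generates radar cubes,
paired reference beat sequences, and multi-evaluation study tables with
known ground truth, so every stage is testable without hardware.

## The processing chain

1. **Phase compensation** — every fast-time sample of frame *t* is rotated
   by −arg *s*₀(*t*), the phase of the static direct-path return in bin 0;
   frame-common phase noise cancels exactly.
2. **Movement screening** — per-second score
   Σₖ |*s*ₖ(*t*) − *s*ₖ(*t*−1)|² thresholded at α × trimmed mean over the
   5-min window (a CA-CFAR rule); flagged seconds are excluded from RR
   construction.
3. **Band-pass** — cascade of linear-phase FIR filters (5 Hz low-pass,
   order 30; 40 beats/min high-pass, order 1000) removes respiration and
   wideband noise with zero group delay.
4. **Vital-bin selection (MP)** — among range bins whose IQ trajectory is
   circle-like, the strongest ring is arctangent-demodulated into a
   displacement-proportional slow-time signal; a classical
   heart-band/noise-band spectral-ratio mode is also provided.
5. **Peak detection** — amplitude-ordered iteration: repeatedly take the
   global maximum of the working signal and zero ±R around it
   (R = half the minimum plausible beat spacing, 57 frames at 250 fps and
   130 bpm), then keep candidates that attain the window maximum of the
   *original* signal.  Peak intervals are the RR intervals.
6. **HRV indices** — mean RR, SDNN, RMSSD (ms); LF (0.05–0.15 Hz) and HF
   (0.15–0.40 Hz) power of the beat-indexed interval spectrum (Hamming
   taper, 2¹⁸-point FFT, no interpolation) and their ratio.
7. **Statistics** — validity screen (radar RMSSD ≤ 100 ms, radar SDNN
   inside the reference range), Pearson r, Bland–Altman bias ± 1.96 SD,
   ICC(2,1) with F-based CI; VAS ≥ 7.5 defines the high-distress group,
   compared by one-way ANOVA and ROC with the top-left optimal threshold.

## Worked example

```sh
python examples/01_simulate_and_recover.py
```

```
scene: 172 fast-time bins x 15000 frames (60 s at 250 fps)
selected fast-time bin MP = 47 (target placed at bin 47)
detected beats: 69 (truth: 73)

index         recovered      truth
mean RR ms       821.53     823.61
SDNN ms           36.54      35.00
RMSSD ms          50.57      48.81
LF/HF              0.45
```

The simulator placed a breathing, beating target at 0.70 m; the pipeline
found the correct fast-time bin from the raw frames and recovered the mean
RR interval within ~2 ms and SDNN within ~5% of the generating truth
(detected-beat count is lower than truth only because the filter's edge
transients are excluded).  The other examples demonstrate movement
exclusion (`02`), agreement statistics over a simulated 102-evaluation
study (`03`), and distress discrimination with ANOVA + ROC (`04`).

A thin CLI wraps the same functions stage by stage:

```sh
pulsebeam simulate --out eval.rcube --truth truth.csv --window-s 60
pulsebeam select eval.rcube --out vital.csv
pulsebeam peaks vital.csv --out peaks.csv
pulsebeam hrv --cube eval.rcube --out indices.json
pulsebeam run --out report/           # full chain incl. study statistics
```

Radar data travels in a self-describing `.rcube` container (JSON header +
raw little-endian complex array) defined in `pulsebeam.radar_model`.

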