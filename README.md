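# eegdyn

Multifaceted EEG-dynamics analysis of endogenous cognitive load:

- **Spectra** — Bartlett-averaged amplitude spectra (1–100 Hz, 1-Hz bins,
  unit-sinusoid scaling), 50-Hz interpolation notch, canonical band
  amplitudes (theta/alpha/beta/gamma), raw and 1/f-free.
- **Aperiodic (1/f) parameterization** — split-band fits (1–25 Hz with up
  to 2 Gaussian peaks, 26–90 Hz with none) of log10-amplitude against
  log10-frequency: offset, exponent, peaks, R², split-half reliability,
  and subtraction of the fitted aperiodic curve.
- **Phase–amplitude coupling** — modulation index (18 phase bins,
  normalized KL divergence from uniform) with a 1–20-Hz phase-
  frequency sweep, plus generalized-Morse-wavelet (γ=3, time-bandwidth 60)
  TFRs averaged after phase synchronization and folded into one-period
  amplitude-vs-phase curves.
- **Group statistics** — 2×IQR outlier exclusion, paired t-tests with
  Cohen's d = t/√n, electrode-cluster permutation tests (≥4 adjacent
  electrodes at p<0.01, half-cohort label reversal, max-|t_sum| null),
  and brain–behavior OLS/Pearson correlation.
- **Behavior** — backward-counting scoring: performance
  (start − final)/decrement, counting frequency, correct-path proxy.
- **Synthetic data** — a ground-truth generator: two-segment 1/f
  backgrounds via spectral shaping, Gaussian oscillation humps with scalp
  gain templates, PAC with controllable modulation depth, and
  cohort-level condition effects with per-participant variability.
- **I/O** — BrainVision (.vhdr/.eeg/.vmrk) reading, an HDF5 container,
  TSV adjacency edge lists, and a built-in 32-channel 10–20 montage with
  a distance-rule adjacency graph.

## CLI

```sh
eegdyn simulate --out cohort/ --participants 4 --seed 1
eegdyn preprocess --in rec.h5 --out proc.h5 --fs 250 --highpass 1
eegdyn spectrum --in proc.h5 --out spectra.tsv
eegdyn aperiodic --spectra spectra.tsv --split 25 --out fits.tsv
eegdyn pac --in proc.h5 --channel Oz --sweep 1 20 0.1 --out mi.tsv
eegdyn cluster-test --features features.tsv --perm 2000 --seed 7 --out clusters.json
eegdyn behavior --in reports.tsv --out scored.tsv
eegdyn adjacency --out adj.tsv
eegdyn run-all --config examples/demo.toml --out results/demo --seed 11
```

`run-all` executes the full synthetic study (simulate → preprocess →
spectra → 1/f fits → PAC → effect sizes/cluster tests → behavior →
correlation) and writes TSV/JSON outputs plus a manifest with per-file
sha256 hashes; a rerun with the same config is bit-identical.

## Notes

- Filters are zero-phase FIR (single-pass, group-delay compensated); the
  default high-pass at 250 Hz uses 827 taps (3.3 s) with its −6 dB point
  at half the pass-band edge.
- Spectrum fits use amplitude (not power) spectra by default; a power
  toggle (`as_power=True`, exponent doubles) is available.
- The built-in adjacency uses pairs closer than 1.3× the median
  nearest-neighbor distance of a schematic head-disc layout; supply your
  own TSV edge list to override.
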