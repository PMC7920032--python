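# neopcg

Quantification of systolic heart murmurs in neonatal phonocardiograms.

Contact-free piezoelectric sensors (PS) placed under a neonate can pick up
chest-wall vibration — including heart sounds and murmurs — without
disturbing the infant, but their output must be quantified objectively
before it is clinically useful. `neopcg` implements the complete analysis
chain for that problem: digital conditioning of the vibration / stethoscope
channels, Hilbert-envelope extraction, ECG-gated segmentation of each beat
into the four cardiac phases (S1, systole, S2, diastole), and a
signal-to-noise statistic that expresses murmur intensity as the mean
systolic envelope amplitude relative to the diastolic noise floor.  A fully
annotated synthetic recording generator stands in for clinical data, so
every stage is testable against known ground truth.

## The statistic

The band-passed heart-sound signal x(t) is turned into its instantaneous
envelope via the analytic signal,

    e(t) = sqrt( x(t)^2 + x̂(t)^2 ),

where x̂ is the Hilbert transform of x.  With each beat segmented into
S1 / systole / S2 / diastole (anchored on the ECG R wave: S1 follows the R
peak, S2 sits between consecutive R waves), the mean envelope amplitudes
S̄1, S̄sys, S̄2, N̄dia over 10 stable consecutive beats give

    SNR_s1  = 20 log10( S̄1   / N̄dia )
    SNR_s2  = 20 log10( S̄2   / N̄dia )
    SNR_sys = 20 log10( S̄sys / N̄dia )   [dB]

A murmur-free recording has SNR_sys near 0 dB; a systolic murmur raises it
in proportion to the murmur's envelope amplitude.  The high-pass cut-off
matters: too low and low-frequency motion noise inflates the diastolic
floor, too high and the murmur itself is removed.  A sweep utility
reproduces this trade-off (the PS optimum sits near 70 Hz).

## Worked example

```python
import neopcg as n

cfg = n.SimConfig(seed=42, murmur_ratio=8.0)      # a Levine ~3 murmur
rec = n.simulate_recording(cfg, subject_id="demo", group="CHD")
for ch in ("stethoscope", "ps"):
    r = n.analyze_recording(rec, ch, hp_cutoff=70.0)
    print(f"{ch:12s}  SNR_s1={r.snr_s1:6.2f} dB  "
          f"SNR_s2={r.snr_s2:6.2f} dB  SNR_sys={r.snr_sys:6.2f} dB")
```

prints

```
stethoscope   SNR_s1= 22.29 dB  SNR_s2= 27.78 dB  SNR_sys= 16.56 dB
ps            SNR_s1= 23.57 dB  SNR_s2= 29.16 dB  SNR_sys= 17.98 dB
```

The generator calibrated the murmur so its systolic envelope is 8× the
diastolic noise floor, i.e. a nominal SNR_sys of 20·log10(8) ≈ 18.06 dB;
both channels recover it to within the pipeline's ~1.5 dB segmentation
bias.  The same pipeline runs from the shell:

```
neopcg simulate --out sim/ --seed 2 --murmur-ratio 6 --group CHD
neopcg analyze --ps sim/s01_ps.wav --ecg sim/s01_ecg.wav
neopcg sweep   --ps sim/s01_ps.wav --ecg sim/s01_ecg.wav
neopcg cohort  --n-chd 9 --n-control 9 --seed 7
```

The `cohort` command simulates nine murmur subjects and nine controls,
analyzes both channels of every subject and runs the group statistics
(exact Mann–Whitney U, Spearman correlation between sensors, linear
regression), e.g.:

```
Cohort analysis
  CHD: n=9, median SNR_sys(PS)=20.72 dB, range [13.52, 24.24]
  control: n=9, median SNR_sys(PS)=2.99 dB, range [2.79, 3.25]
  Mann-Whitney U=81, two-sided p=4.11e-05 *
  Spearman rho=0.965, p=1.03e-10 *
  Regression: PS = 1.058 x stethoscope + 0.303
```

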