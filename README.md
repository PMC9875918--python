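# prepair

Unsupervised physiological noise correction for BOLD fMRI from the phase
and magnitude of EPI time series (PREPAIR: Physiological Regressor
Estimation from Phase and mAgnItude, sub-tR).

## The problem

Respiration and the cardiac cycle are the dominant noise sources in
resting-state and task fMRI, especially at high field. Chest motion
modulates the B0 field — which the *phase* of the complex EPI signal sees
directly — while pulsatile flow and spin-history effects modulate the
*magnitude*, mainly in voxels near vessels. Conventional corrections
either need external recordings (belt, plethysmograph), which are
unreliable and awkward to integrate, or mine the magnitude data alone and
struggle because cardiac rates (≈ 1–1.6 Hz) are aliased at typical volume
repetition times.

PREPAIR removes both obstacles:

1. **Sub-TR sampling.** High-SNR voxels are averaged per slice, each
   slice's series is detrended with a third-order polynomial, and the
   per-slice series are re-interleaved according to the slice acquisition
   order (simultaneous-multislice groups averaged). This yields one scalar
   series of length NR·NS sampled at NS/TR<sub>vol</sub> Hz (NS = N/MB
   excitations per TR), fast enough to critically sample cardiac
   fluctuations.
2. **Fundamental identification with sideband rejection.** Band-pass
   prefilters ([9–30] cpm respiratory, [42–96] bpm cardiac, second-order
   zero-phase Butterworth) isolate candidate spectra. Re-interleaving
   creates a carrier at f<sub>1/TR</sub> = 1/TR<sub>vol</sub>; amplitude
   modulation by respiration or by the scanner's cold-head helium pump
   (f<sub>pump</sub> ≈ 0.13 Hz) produces sidebands S = k·f<sub>1/TR</sub> ±
   f<sub>m</sub> that can out-power the true cardiac line. These predicted
   frequencies are zeroed in the power spectrum (not band-pass filtered, to
   spare nearby signal) and the strongest surviving in-band peak, refined
   by parabolic interpolation, gives f<sub>R</sub> and f<sub>C</sub>.
3. **Source selection.** Narrowband waveforms (f<sub>R</sub> ± 2.5 cpm,
   f<sub>C</sub> ± 6.5 bpm) are extracted from both magnitude and phase;
   for each noise type the source whose two-harmonic Fourier regressors
   explain more variance is kept. In practice phase wins for respiration
   and magnitude usually wins for cardiac.
4. **Slice-wise RETROICOR-style regression.** Cycle phases (peak-to-peak
   for cardiac, amplitude-histogram for respiration) are expanded as
   sin kφ, cos kφ (k = 1, 2) at each slice's own acquisition times, and
   the fitted physiological part — orthogonalized against a retained
   polynomial drift basis — is subtracted voxel-by-voxel.

A synthetic EPI generator with known ground truth (quasi-periodic
oscillators, vessel compartment, pump line with slice-dependent coupling,
drift, thermal noise, optional phase wrapping) plus the evaluation metrics
(lag-aware correlation with external recordings, band-power removal
proportion, out-of-band power fluctuation, tSNR gain, 45 s/4 s sliding
spectrograms) make the whole method testable without scanner data.

## Worked example

```python
from prepair import run_prepair, simulate_epi, simulate_external
from prepair.simulate import default_config
from prepair.pipeline import assess_correction
from prepair.evaluate import waveform_external_correlation

series, truth = simulate_epi(default_config(seed=1))   # 32x32x12, NS=6, 300 s
result = run_prepair(series)
report = assess_correction(series, result)
recording = simulate_external(truth)                   # 1/400 s belt + pleth
```

Printing the key fields gives:

```
respiration: source=phase, f_R=0.2501 Hz
cardiac:     source=magnitude, f_C=1.1695 Hz
pump line:   0.1299 Hz
resp waveform vs belt: r=1.000 at lag 0.00 s
resp band power removed:    0.92
cardiac band power removed: 0.85
out-of-band change:         +0.006
median tSNR gain in mask:   43.0%
```

The generator injected respiration at 0.25 Hz (phase-dominant), cardiac at
1.17 Hz (magnitude, vessel voxels) and a 0.13 Hz pump line in phase; the
pipeline recovered all three frequencies to sub-bin precision, chose the
correct source for each noise type, removed ~90% of respiratory and ~85%
of cardiac band power while changing out-of-band power by under 1%.

## Command line

```bash
prepair simulate --seed 1 --out sim/                  # synthetic run + ground truth
prepair run --magnitude sim/magnitude.nii.gz --phase sim/phase.nii.gz \
            --tr 1.0 --slices 12 --mb 2 --out out/ --report
prepair eval --before sim/magnitude.nii.gz --after out/corrected.nii.gz \
             --tr 1.0 --slices 12 --mb 2 --regressors out/regressors.tsv \
             --out eval/
```

`run` writes the corrected 4D NIfTI, an R² map, the slice-wise regressor
table (TSV + JSON sidecar with chosen sources, fundamentals and bands) and
optional spectral reports.

## Documentation

See `docs/methods.md` for the model, parameter defaults and units, what
the synthetic generator does and does not emulate, numerical choices and
known limitations.
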