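# Methods

This note documents the model and procedure implemented by `prepair`, the
defaults and their units, what the synthetic generator emulates, the
numerical choices, and the design decisions taken where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Signal model

The magnitude of a resting EPI voxel is modelled as a baseline intensity
multiplicatively modulated by respiration (globally) and by cardiac
pulsation (in vessel-adjacent voxels), plus slow scanner drift and
thermal noise. The phase of the complex EPI signal responds to bulk B0
changes: strongly to chest motion at the respiratory frequency, weakly to
cardiac pulsation, and — on some scanners — to a narrowband cold-head
helium-pump disturbance near 0.1–0.2 Hz. Both noise types are
quasi-periodic: an instantaneous frequency wandering around a base rate,
integrated to phase.

The correction models each noise type retrospectively as a low-order
Fourier series of its cycle phase φ(t),

    y_phys(t) = Σ_{k=1,2} a_k sin kφ(t) + b_k cos kφ(t),

evaluated at each slice's own acquisition times (slice-wise regressors;
slices excited together share regressors), and removes the fitted part by
ordinary least squares per voxel.

## Sub-TR extraction

Per data source (magnitude; phase, if provided):

1. **Mask.** Voxels whose temporal-mean magnitude exceeds 20% of the
   robust maximum, defined as the 98th percentile (linear-interpolation
   convention) of the temporal-mean image. The percentile is deliberately
   computed on the temporal-mean image, one value per voxel, rather than
   on all voxel-time samples; the two readings differ negligibly for
   stationary data and the per-voxel reading matches the criterion's
   "mean intensity over time". An alternative absolute-intensity mode
   (default threshold 3000) suits partial-coverage acquisitions such as
   brainstem slabs, and a user-supplied mask overrides both.
2. **Slice averaging.** Plain mean over masked voxels for magnitude;
   magnitude-weighted mean Σ m·φ / Σ m for phase (one common mask for
   both). Slices with empty masks are filled from the nearest non-empty
   slice with a warning rather than failing, so partial-coverage runs
   complete unattended.
3. **Detrending.** A third-order polynomial is fitted (least squares on a
   rescaled time axis for conditioning) and subtracted per slice row,
   removing the slice-dependent baseline — the dominant source of the
   re-interleaving carrier — and slow drift. Phase rows are treated
   identically to magnitude rows.
4. **Reordering.** Rows of simultaneously excited slices are averaged
   (unweighted) to NS = N/MB group rows, which are interleaved in
   excitation order, giving NR·NS samples at NS/TR_vol Hz. Excitations
   are assumed uniformly spaced within the TR (t = g·TR_vol/NS for group
   rank g) unless explicit offsets are supplied; acquisition protocols
   rarely publish intra-TR timing and uniform spacing with zero dead time
   is the natural default. Slice order defaults to sequential ascending
   with SMS grouping {g, g+NS, …}; any order can be given explicitly.

A per-voxel temporal unwrap (differences folded into |Δ| ≤ π) is applied
to wrapped phase as a fallback; it cannot repair wraps faster than half a
cycle per sample, for which spatially unwrapped input should be supplied
instead.

## Fundamental identification

Respiration first: the sub-TR series is prefiltered to [9–30] cpm with a
zero-phase (forward–backward) second-order Butterworth band-pass, and the
strongest peak in the band is taken. Filters are applied
forward–backward so the waveform remains time-aligned with the slice
acquisition times.

Pump line (phase source only): presence is decided on a Welch-averaged
spectrum — the strongest bin in [0.08, 0.2] Hz outside the respiratory
notch f_R ± 2.5 cpm must exceed 3× the median in-band power. The
averaging matters: on a raw periodogram the noise-bin maximum of a
pump-free band routinely exceeds 3× the median (exponential bin
statistics), which would make the detector fire on clean data. When
present, the frequency is refined on the full-resolution periodogram.
If the detected pump lies outside the respiratory notch, respiration is
re-identified with the pump line excluded, covering protocols where the
pump intrudes into the respiratory band.

Cardiac: the search band [42–96] bpm is widened by 10% at both edges so
unusual rhythms near the limits are not cut off by the gentle
second-order prefilter. The re-interleaving carrier k/TR_vol (k up to
the harmonic reaching the band, capped at 4), amplitude-modulated by
respiration and the pump, predicts sidebands S = k/TR_vol ± f_m; a notch
of halfwidth max(2 spectral bins, 0.01 Hz) around each predicted sideband
is zeroed in the spectrum — zeroed, not filtered, so nearby genuine
content survives — and the search iterates until the maximum falls
outside every notch. Peaks are refined by parabolic interpolation on
log-power (clamped to ±half a bin, falling back to the bin centre at
edges or zeroed neighbours); the refined value is rejected if it lands
inside a notch.

Narrowband waveforms are then extracted around the fundamentals with the
same zero-phase filter: f_R ± 2.5 cpm and f_C ± 6.5 bpm, clipping at the
Nyquist limit with a warning.

## Source selection

For each noise type the magnitude- and phase-derived candidates are
scored by the fraction of variance their two-harmonic regressors (plus
intercept) remove from a target series, and the higher-scoring source is
kept. The default target is the candidate's **own** source's sub-TR
series. The obvious alternative — scoring both candidates against the
magnitude series, since magnitude images are what get corrected — fails
a basic sanity requirement: when respiration is absent from the
magnitude data entirely, a narrowband-filtered copy of magnitude noise
always "explains" the magnitude series better than a clean respiratory
waveform from phase, so the selector would reject the only informative
source exactly when it matters most. Scoring each candidate on its own
source measures how strongly that source expresses the physiological
process, which is the quantity of interest; the magnitude-target variant
remains available (`target_mode="magnitude"`). Ties within 1e-9 break to
phase for respiration and magnitude for cardiac, the empirically better
source for each kind.

## Cycle phases and correction

Cardiac phase is peak-to-peak: peaks of the narrowband waveform
(minimum separation half a period, prominence 0.25× RMS, parabolic time
refinement) define φ rising linearly 0 → 2π between consecutive peaks,
with nearest-period extrapolation outside. Respiratory phase uses the
amplitude-histogram convention φ = π·H(a)·sgn(da/dt) mapped into
[0, 2π), H being the 100-bin empirical CDF of the waveform amplitude —
this distinguishes inspiration from expiration and weights by occupancy
of the amplitude range. A config switch (`phase_convention="peaks"`)
forces peak-to-peak phase for both kinds.

Correction is per slice: the 8 regressor columns are orthogonalized
against a Legendre drift basis (order 3, matching the extraction
detrend), each masked voxel is fitted by OLS, and only the physiological
fit is subtracted — drift and mean stay in the data. Orthogonalization
guarantees the per-voxel variance can never increase and makes the
correction idempotent; its flip side is that the drift-collinear part of
a regressor is deliberately retained (it is attributed to drift, which
the correction promises not to touch). Numerically dependent columns are
dropped with a warning. Out-of-mask voxels are returned bit-identical.

## Evaluation metrics

* **Waveform fidelity.** External recordings are linearly interpolated to
  the sub-TR times and band-passed with the identical narrowband filter
  before the lag-aware correlation (maximum-magnitude normalized
  cross-correlation over ±5 s, clipped to keep ≥ 32 overlapping samples).
* **Band power.** Voxelwise spectra are computed at the volume rate
  1/TR_vol (voxels cannot be super-sampled); bands above the volume
  Nyquist are mapped through aliasing (a bin g is in-band iff k·f_s ± g
  falls in the band for some integer k). The removal proportion is
  1 − P_after/P_before over the in-band bins. The slice average weights
  voxels by their in-band power before correction — equivalently, the
  relative change of slice-pooled band power — because a uniform mean
  over voxels lets the many voxels that never contained the noise dilute
  the statistic toward zero; `weighting="uniform"` provides the
  unweighted per-voxel mean. The second-harmonic band 2f_0 ± halfwidth is
  included when present in the data: its pooled power density must exceed
  1.2× a robust background (median per-bin density outside the band),
  rather than flanking bands, which the aliased cardiac fundamental can
  contaminate at ordinary TRs.
* **Integrity.** The same statistic over the complement of the
  physiological bands (DC excluded); near zero means out-of-band signal
  was preserved.
* **tSNR.** Temporal mean/SD per voxel before and after, percentage gain
  where defined, with 25/50/75th-percentile ROI summaries.
* **Spectrograms.** 45 s windows stepped by 4 s; within each window three
  50%-overlapping Hann-tapered segments are Welch-averaged — a simple
  variance-reduced estimator standing in for multitaper averaging.

## Synthetic generator

`simulate_epi` produces a smooth blob "brain" (peak 1000, ~0.55 of peak
averaged over the mask) with per-slice baseline offsets (SD 30), cubic
per-slice drift (coefficient SD 5), a 15% vessel compartment, Gaussian
noise, and the physiological signals above; the same oscillators drive
`simulate_external` at 1/400 s. Oscillator phases integrate
base + AR(1) jitter (coefficient 0.99 on a 0.1 s control grid, stationary
SD from config). Defaults (units in the dataclass):

| parameter | default | meaning |
|---|---|---|
| grid / timing | 32×32×12, MB 2, TR 1 s, NR 300 | NS = 6, sub-TR rate 6 Hz |
| resp | 0.25 Hz, jitter SD 0.003 Hz | 0.2 rad in phase, 2% of baseline in magnitude |
| cardiac | 1.17 Hz, jitter SD 0.003 Hz | 6% of baseline in vessel voxels, 0.02 rad in phase, 30% second harmonic |
| pump | 0.13 Hz, 0.05 rad | phase only, slice-dependent coupling (±50%) |
| noise | magnitude SD 5, phase SD 0.05 rad | mask-mean thermal tSNR ≈ 100 |

The defaults portray a calm, regular resting subject: jitter SDs are set
so the run-averaged frequency stays within one spectral bin (1/300 Hz) of
the base rate, making "the generator's frequency" well defined for
recovery checks; irregular breathing (spreads up to ±2.5 cpm) is
reachable by raising the jitter. Slice-dependent coupling of the phase
modulators is what creates the reordering sidebands k/TR ± f_m; the
default is a seeded random per-slice profile, while the sideband stress
preset uses a deterministic cosine profile over excitation groups — a
worst-case pattern whose carrier Fourier coefficient survives SMS
averaging for every seed, with a strong pump (0.25 rad) and weak cardiac
phase (0.02 rad) so the sideband genuinely out-powers the true line.
In that preset the cardiac base is 1.0 Hz, kept well clear of the
respiratory sideband 1/0.7 − f_R ≈ 1.18 Hz so that "the true cardiac
line" is not itself inside an exclusion notch.

What the generator does **not** emulate: motion, EPI ghosting and
distortion, multi-coil combination residuals, spatially structured
(non-global) phase noise, BOLD signal and slow network fluctuations,
heavy-tailed or Rician noise (magnitude is Gaussian, clipped at zero
outside the brain), and respiratory-volume/heart-rate-variability
low-frequency effects. Passing tests therefore demonstrate the
correctness of the algorithmic chain under its stated signal model, not
performance on acquired human data.

## Numerical choices and degenerate inputs

* Spectra use mean-removed boxcar periodograms with `spectrum` scaling
  (bin powers sum to the variance); spectral resolution is rate/length.
* Butterworth filters are order 2, applied with `sosfiltfilt`; bands are
  validated against the Nyquist limit and narrowbands are clipped with a
  warning.
* The percentile in the mask uses the linear-interpolation convention and
  is tested against a sort-based oracle.
* Zero-variance waveforms, constant signals, all-zero magnitude, bands
  outside Nyquist, non-monotone peak lists and exhausted search bands
  raise typed errors (`prepair.errors`); pump absence returns `None`
  rather than raising.
* Everything is deterministic given the inputs; the only randomness lives
  in the generator and is fully driven by its seed.

## Problem sizes

The test suite and acceptance script run the reference grid (32×32×12,
300 volumes) and the stress scenarios (20 slices at TR 2 s; 48 slices,
MB 8 at TR 0.7 s), with 10–50 seeded replicates per property — sizes at
which every spectral feature of interest (carrier, sidebands, aliased
cardiac line) is resolved while a full run of the battery stays within a
few minutes on one CPU.

## Known limitations

* A single fundamental per run: strongly non-stationary heart or
  breathing rates are represented only within the ±halfwidth narrowband;
  no instantaneous-frequency tracking.
* The temporal phase unwrap cannot recover wraps faster than half a cycle
  per sample; spatially unwrapped phase input is preferred.
* Slice-wise regressors are produced for every slice; downsampling to a
  single reference slice (as some toolboxes default to) is out of scope —
  users wanting reference-slice behaviour can take the middle slice's
  matrix from the regressor table.
* The respiratory-band search assumes the pump line and respiration do
  not coincide; if they overlap within the notch width the two are not
  separable from a single run.
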