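# Methods

`nirsleep` analyzes task-free (sleeping-infant) continuous-wave fNIRS
recordings: dual-wavelength light intensities from a 52-channel cap are turned
into oxy-/deoxyhemoglobin concentration changes, and the cohort is compared
between sexes through power spectral densities, channel-wise significance
tests, Pearson functional-connectivity matrices, and the Hilbert-phase
HbO–HbR difference statistic (hPod). A synthetic cohort generator reproduces
the statistical structure of such a cohort so that every stage can be verified
against known ground truth. This note records the models, the defaults and why
they were chosen, the numerical decisions, and the known limits of what the
synthetic verification shows.

## Montage

The cap carries 16 sources and 24 detectors; each adjacent source–detector
pair defines one of 52 measurement channels, numbered so that left-hemisphere
channels 1–26 mirror right-hemisphere channels 27–52 (homotopic pairs
(i, i+26)). Six occipital channels are flagged and excluded — the back of a
sleeping infant's head rests against the parent, so those optodes are
unreliable — leaving 46 analyzed channels that touch 14 sources and
19 detectors. Published descriptions of such caps give only a 2-D schematic,
so the packaged montage is a reconstruction: its combinatorics
(52/46 channels, 16/24 optodes, 14/19 surviving, the (i, i+26) homotopy) are
exact, while the normalized planar positions and the identity of the six
excluded channels are plausible rather than authoritative. Analyses bind to
the combinatorics; positions are used only for topographic display, which
interpolates per-channel scalars by inverse-distance weighting (power 2).

## Preprocessing

1. **Optical density.** ΔOD(t, ch, λ) = −ln(I(t, ch, λ) / Ī(ch, λ)), with the
   channel's temporal mean intensity as reference. Scattering losses are
   time-invariant and cancel in this differential form; consequently all
   concentrations are determined only up to a per-channel constant, and
   round-trip tests compare mean-removed series.
2. **Wavelet motion-artifact suppression.** Each channel/wavelength series is
   decomposed (Daubechies-4, 5 levels, symmetric extension); detail
   coefficients farther than 1.5 interquartile ranges from their per-level
   median are set to zero before reconstruction. Motion spikes concentrate in
   sparse large detail coefficients while the oscillatory physiology does not,
   so the rule removes spikes with little distortion; with thresholding
   disabled the transform reconstructs the input to ~1e−12.
3. **Modified Beer–Lambert inversion.** Per time point and channel the 2×2
   system ΔOD(λᵢ) = D(λᵢ)·x·[ε_HbO(λᵢ), ε_HbR(λᵢ)]·[ΔHbO, ΔHbR] is solved
   exactly. Defaults: wavelengths 760/850 nm, differential path-length factors
   (5.3, 4.2) appropriate for the 4-month-old head, separation x = 3.0 cm,
   standard tabulated extinction coefficients. Because only relative changes
   are analyzed, x (and any overall amplitude scale) cancels out of PSD shape,
   correlations, phases and t statistics; tests assert this scale invariance,
   and every exactness test passes explicit matrices so no literature value is
   load-bearing. Inversion refuses matrices with condition number above 1e8.
4. **Nuisance regression.** Ordinary least squares against Legendre
   polynomials of order 0–4 on time rescaled to [−1, 1] (slow drift),
   sine/cosine pairs at the discrete Fourier frequencies inside configured
   physiological-noise bands at/above 0.09 Hz (default bands 1.5–2.5 and
   3.5–4.5 Hz, i.e. cardiac fundamental and harmonic), and optionally the
   mean series over retained channels (global systemic signal). Placing
   sinusoids at *every* Fourier frequency ≥ 0.09 Hz is available
   (`frequency_mode="all"`) but flagged as aggressive: it projects out
   essentially the whole spectrum above the cutoff. Residuals are orthogonal
   to the design to < 1e−8 relative, and the operator is idempotent.

**Where regression sits in the pipeline.** The nuisance bands deliberately
target the cardiac oscillation, which is *signal* for the spectral analysis:
regressing it out first would erase the 2 Hz / 4 Hz peaks the PSD stage
characterizes. The pipeline therefore computes PSDs and hPod on data that are
OD-converted, wavelet-denoised and Beer–Lambert-inverted but *not*
nuisance-regressed, and applies nuisance regression (drift, cardiac bands,
global signal) before the functional-connectivity and activation-map stages,
where systemic components would otherwise inflate inter-channel correlations.

**Activation maps.** Group "activation" maps display a per-channel scalar on
the cap via inverse-distance interpolation. Because optical-density conversion
references each channel's temporal mean, the concentration time-averages are
zero by construction; the pipeline therefore maps the per-channel RMS
amplitude of the (nuisance-regressed) signals, a magnitude measure that is
well defined for differential data.

## Spectral analysis

Per-subject and per-channel PSDs use Welch's method (Hann, 60 s segments, 50%
overlap; frequency resolution ≈ 0.0167 Hz at fs = 15.625 Hz); a plain
periodogram (Parseval-consistent within 1%) serves analytic tests. The
display band is 0–4.5 Hz. Group curves come in two forms: the *spectrum of
the average signal* (average each subject's channel-averaged series, then one
PSD — the default, mirroring an analysis that Fourier-transforms group-mean
traces) and the *average of per-subject spectra*. For localizing group peaks
the package uses the average-spectra curve: its estimator variance falls as
1/√n_subjects, whereas the averaged-signal spectrum is a single noisy
realization.

A group curve near the cardiac frequency is a superposition of narrow
per-subject lines (between-subject cardiac s.d. 0.1 Hz), so a raw argmax
follows whichever lines happen to coincide. `peak_frequency` therefore
smooths the linear power over ≈ 0.3 Hz, takes the band argmax, and refines it
with a power-weighted centroid of the floor-subtracted power within ±0.35 Hz
(floor = median band power). On default-size cohorts this tracks the
population mean component frequency to well under one frequency bin; the
residual error is dominated by the sampling error of the realized cohort mean
(≈ 0.1/√99 ≈ 0.01 Hz for the fundamental, twice that for the harmonic).

`estimate_frequency_shift` reports the displacement between two group curves.
The default method is the difference of the two centroid-refined peak
frequencies, which on simulated 200-per-group cohorts reproduces the realized
group frequency difference to ≈ 0.003 Hz. Lag-maximizing cross-correlation of
the smoothed log curves is retained as `method="xcorr"`; it is shape-agnostic
but acquires a bias of up to a couple of bins when the displaced peak rides
on an undisplaced background (1/f tail, noise floor), which is why it is not
the default.

## Functional connectivity

FC matrices are Pearson correlations between channel time courses, for
HbO×HbO, HbR×HbR, HbT×HbT (symmetric, unit diagonal) and the generally
asymmetric HbO×HbR cross matrix, whose diagonal — a channel's own HbO–HbR
correlation — is negative for near-antiphase physiology. Group averaging
applies Fisher's z entrywise before the mean (correlations are bounded, so
their direct mean is biased toward zero); plain averaging is available.
Channels with zero variance are flagged invalid and excluded from strength
summaries instead of propagating NaN. Connectivity strength is the mean
off-diagonal correlation of a channel's row; the homotopic profile extracts
the (i, i+26) entries.

## hPod

For each channel, HbO and HbR are band-pass filtered (default 0.01–0.5 Hz —
the respiratory/Mayer/vasomotion range; instantaneous phase is only
meaningful for narrowband signals, and no published band exists for this
statistic, so the default is a documented reconstruction), Hilbert-
transformed, and the instantaneous phase difference φ_HbO − φ_HbR is averaged
over time. The average is a *circular* mean (direction of the mean unit
vector): an arithmetic mean of wrapped differences is biased exactly where
the statistic concentrates (≈ 180°). Five percent of samples are trimmed at
each edge against Hilbert end effects. The identities hpod(x, x) = 0° and
hpod(x, −x) = 180° hold to numerical precision regardless of filtering, and
the statistic is invariant to positive amplitude rescaling. Histograms use
30° bins (matching the granularity at which such distributions are reported);
the sex comparison is a Welch two-sample t-test on subject-level circular
means represented on the branch [0°, 360°), whose discontinuity sits farthest
from the 180° physiological center.

## Channel-wise significance testing

Two modes compare the sexes per channel:

- **paired-over-frequency** (default, mirroring the described group
  procedure): a paired t-test across frequency bins of the two group-mean
  log₁₀-PSD curves in the analysis band. Because adjacent Welch bins are
  correlated and group-mean curves carry smooth between-subject structure,
  the bins are not independent samples; measured on null cohorts this mode is
  markedly anti-conservative (type-I error far above alpha). It is retained
  as a descriptive, literature-mirroring mode.
- **band-power**: each subject's log₁₀ band-integrated power is the sampling
  unit, compared by Welch's unequal-variance t-test. Measured type-I error is
  0.039–0.053 across group sizes 8–24 per sex, converging to the nominal 0.05
  as groups grow; this is the mode used for all quantitative claims.

No multiplicity correction is applied by default (raw p < 0.05 over the 46
channels, as in the analysis being mirrored); Benjamini–Hochberg is available
and both versions appear in the pipeline report. For replicated simulation
experiments, `replicate_median_significance` thresholds each channel's
*median* p-value across replicate cohorts: channels carrying a real effect
have median p ≈ 0, null channels ≈ 0.5, so the aggregate identifies exactly
the effect set once per-replicate power is high — any calibrated test at
alpha = 0.05 must flag ≈ 0.05 × 42 null channels *per replicate*, so a
per-replicate count can never be exactly the effect-set size on average.

## Synthetic cohort generator

Defaults emulate the study cohort: 51 female / 48 male subjects, 540 s at
15.625 Hz on the 52-channel montage. Per subject and channel, ΔHbO is a sum
of a cardiac sinusoid (subject frequency ~ N(2.0, 0.1) Hz, amplitude
0.08 µM), its first harmonic at half amplitude, a respiratory component
(~ N(0.35, 0.05) Hz, 0.25 µM), a 0.1 Hz Mayer wave (0.30 µM), 1/f drift plus
a gentle polynomial trend (0.30 µM scale), and white noise (0.15 µM). ΔHbR is
a 0.3-amplitude copy of the oscillatory components rotated by the subject's
per-channel hPod angle (~ N(190°, 10°)), plus its own drift and noise — i.e.
near-antiphase chromophores with negative HbO–HbR correlation. Component
phases are shared across channels up to a per-channel dispersion (0.6 rad),
with homotopic partners coupled (ρ = 0.6), producing positive inter-channel
FC and a homotopic excess. Optional sparse motion artifacts are
Poisson-timed (0.2/min) Gaussian bumps with exponential amplitude (2 µM
scale) and per-channel gain — the standard fNIRS motion caricature. Group
effects multiply the oscillatory amplitude of one chromophore on selected
channels for one sex. Concentrations are mapped through the forward
modified Beer–Lambert model to strictly positive intensities (median
modulation ~1–2% of baseline, worst-case drift tails below 10%). A male
cardiac offset (e.g. +0.05 Hz) exists solely to exercise the shift
estimator. All draws descend from one master seed via SeedSequence spawning;
cohorts are bit-reproducible.

What the generator does *not* emulate: sleep-stage cycling and
non-stationarity, vascular compliance and neurovascular coupling dynamics,
layered-tissue photon transport, heteroscedastic channel quality, or any true
sex difference beyond what is injected. Passing tests therefore demonstrate
that the pipeline recovers known structure of this class — periodic
physiology, near-antiphase chromophores, injected amplitude effects — not
that the original infant findings replicate.

## Problem sizes used in verification

Chosen so the full suite runs comfortably on one CPU:

- spectral structure and hPod recovery: the full default cohort (99 subjects
  × 9 min × 46 channels, seed 0);
- channel-effect recovery: 20 replicate cohorts of 26 F / 24 M with a 2×
  HbO amplitude effect on channels 1, 21, 32, 39 (male group);
- null calibration of the band-power test: 200 replicate cohorts of
  15 F / 15 M at 120 s (t-test calibration is a group-size property, so the
  check runs at reduced size);
- frequency-shift recovery: 200 subjects per sex at 60 s, so the sampling
  error of the group mean frequency (0.1/√200) sits below one frequency bin;
- hPod sex-difference null: 50 replicate cohorts of 12/12 at 120 s.

## Known limitations

- The montage geometry is a reconstruction; only its combinatorics are exact.
- The paired-over-frequency test mode is anti-conservative and should not be
  used for inference; it exists to mirror a described procedure.
- hPod depends on the (configurable) pre-Hilbert band; very short recordings
  (< ~2 min) leave few slow-oscillation cycles and noisier angles.
- The SNIRF layer covers continuous-wave amplitude recordings with 2-D probe
  geometry, not the full format (no auxiliary channels, no 3-D landmarks).
- Occipital-channel identification, extinction coefficients and optode
  wavelengths are configurable defaults, not measured properties of any
  specific instrument.
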