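"""Synthetic sleeping-infant fNIRS cohorts with known ground truth.

The generator emulates the statistical structure the analysis pipeline assumes
for a task-free cohort of 4-month-old infants recorded during natural sleep:

* 51 female / 48 male subjects, >= 9 min at 15.625 Hz on the 52-channel cap;
* a cardiac oscillation near 2 Hz (between-subject s.d. 0.1 Hz) plus its first
  harmonic at half amplitude, a respiratory component near 0.35 Hz, a ~0.1 Hz
  Mayer wave, 1/f + polynomial drift, and white measurement noise;
* HbR as a 0.3-amplitude, phase-rotated copy of the HbO oscillations realizing
  a per-channel HbO-HbR phase difference (hPod) of 190 deg +/- 10 deg, i.e.
  near-antiphase chromophores with negative HbO-HbR correlation;
* oscillation phases shared across channels up to a per-channel dispersion,
  with homotopic channel pairs more tightly coupled than arbitrary pairs;
* optional sparse motion artifacts (Poisson-timed bumps with exponential
  amplitude) and per-channel group amplitude effects for power-difference
  experiments.

Concentrations are pushed through the forward modified Beer-Lambert model to
strictly positive dual-wavelength intensities (modulation depth well under 5%
of baseline), so every pipeline stage from raw light onward can be exercised.
All randomness flows from a single master seed via numpy SeedSequence spawning,
so a cohort is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Sequence

import numpy as np

from .exceptions import CohortSpecError
from .montage import Montage, default_montage
from .preprocess import DEFAULT_CONSTANTS, OpticalConstants, RawIntensityRecording

__all__ = [
    "GroupEffect",
    "CohortSpec",
    "GroundTruth",
    "generate_subject",
    "generate_cohort",
    "iter_cohort",
    "inject_group_effect",
]


@dataclass(frozen=True)
class GroupEffect:
    """Multiply the oscillatory amplitude of one chromophore on some channels
    for one sex by ``scale`` (power scales by scale**2)."""

    channels: tuple[int, ...]
    chromophore: str  # "HbO" | "HbR"
    sex: str  # "female" | "male"
    scale: float


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterization of the synthetic cohort generator."""

    n_female: int = 51
    n_male: int = 48
    duration_s: float = 540.0
    fs: float = 15.625
    cardiac_hz: float = 2.0
    cardiac_sd: float = 0.1
    cardiac_male_offset_hz: float = 0.0
    harmonic_ratio: float = 0.5
    respiratory_hz: float = 0.35
    respiratory_sd: float = 0.05
    mayer_hz: float = 0.1
    hbr_ratio: float = -0.3
    hpod_deg: float = 190.0
    hpod_jitter_deg: float = 10.0
    cardiac_amp: float = 0.08     # umol/L amplitudes
    respiratory_amp: float = 0.25
    mayer_amp: float = 0.30
    drift_sd: float = 0.30
    noise_sd: float = 0.15
    artifact_rate_per_min: float = 0.2
    artifact_amp: float = 2.0
    artifact_width_s: float = 0.4
    phase_dispersion_rad: float = 0.6
    homotopic_coupling: float = 0.6
    gain_sd: float = 0.2
    effects: tuple[GroupEffect, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_female < 0 or self.n_male < 0 or self.n_female + self.n_male == 0:
            raise CohortSpecError("cohort must contain at least one subject")
        if self.duration_s <= 0 or self.fs <= 0:
            raise CohortSpecError("duration and sampling rate must be positive")
        nyq = self.fs / 2
        for f in (2 * self.cardiac_hz, self.respiratory_hz, self.mayer_hz):
            if not (0 < f < nyq):
                raise CohortSpecError(f"component frequency {f} Hz outside (0, Nyquist)")
        if abs(self.hbr_ratio) <= 0:
            raise CohortSpecError("hbr_ratio must be nonzero")
        retained = set(default_montage().retained_ids)
        for e in self.effects:
            if e.scale <= 0:
                raise CohortSpecError("effect scale must be positive")
            if e.chromophore not in ("HbO", "HbR"):
                raise CohortSpecError(f"unknown chromophore {e.chromophore!r}")
            if e.sex not in ("female", "male"):
                raise CohortSpecError(f"unknown sex {e.sex!r}")
            bad = set(e.channels) - retained
            if bad:
                raise CohortSpecError(f"effect channels not retained: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return int(np.ceil(self.duration_s * self.fs))

    @property
    def n_subjects(self) -> int:
        return self.n_female + self.n_male


@dataclass(frozen=True)
class GroundTruth:
    """Generator state for one subject, stored losslessly for verification."""

    subject_id: str
    sex: str
    cardiac_hz: float
    respiratory_hz: float
    hpod_deg: np.ndarray                 # per-channel target angle
    hbo_scale: np.ndarray                # per-channel amplitude effect, HbO
    hbr_scale: np.ndarray
    clean_hbo: np.ndarray | None = None  # oscillation+drift, before noise/artifacts
    clean_hbr: np.ndarray | None = None


def inject_group_effect(
    spec: CohortSpec,
    channels: Sequence[int],
    chromophore: str,
    sex: str,
    scale: float,
) -> CohortSpec:
    """Return a spec whose effect table additionally scales the oscillatory
    amplitude of ``chromophore`` on ``channels`` for ``sex`` by ``scale``."""
    eff = GroupEffect(tuple(int(c) for c in channels), chromophore, sex, float(scale))
    return replace(spec, effects=spec.effects + (eff,))


def _pink_noise(rng: np.random.Generator, n: int, n_ch: int) -> np.ndarray:
    """1/f-amplitude noise, unit variance per channel, shape (n, n_ch)."""
    from scipy import fft as sfft

    nf = sfft.next_fast_len(n)  # pad: arbitrary n can hit slow prime-length FFTs
    white = rng.standard_normal((nf, n_ch))
    spec = sfft.rfft(white, axis=0)
    f = np.fft.rfftfreq(nf)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** -0.5
    scale[0] = 0.0
    x = sfft.irfft(spec * scale[:, None], n=nf, axis=0)[:n]
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return x / sd


def _channel_phase_offsets(
    rng: np.random.Generator, m: Montage, dispersion: float, coupling: float
) -> np.ndarray:
    """Per-channel phase offsets with homotopic pairs coupled."""
    n = m.n_channels
    off = m.homotopic_offset
    base = rng.standard_normal(n)
    if n == 2 * off and 0 < coupling <= 1:
        extra = rng.standard_normal(off)
        base[off:] = coupling * base[:off] + np.sqrt(1 - coupling**2) * extra
    return dispersion * base


def generate_subject(
    spec: CohortSpec,
    subject_index: int,
    sex: str,
    seed: int | np.random.SeedSequence,
    constants: OpticalConstants = DEFAULT_CONSTANTS,
    montage: Montage | None = None,
    store_clean: bool = True,
) -> tuple[RawIntensityRecording, GroundTruth]:
    """One subject's raw dual-wavelength recording plus its ground truth."""
    m = montage or default_montage()
    rng = np.random.default_rng(seed)
    n = spec.n_samples
    n_ch = m.n_channels
    t = np.arange(n) / spec.fs

    mu_card = spec.cardiac_hz + (spec.cardiac_male_offset_hz if sex == "male" else 0.0)
    f_card = float(np.clip(rng.normal(mu_card, spec.cardiac_sd),
                           0.5, spec.fs / 4 - 1e-3))
    f_resp = float(np.clip(rng.normal(spec.respiratory_hz, spec.respiratory_sd),
                           0.05, 0.5))
    f_mayer = spec.mayer_hz
    theta = np.deg2rad(rng.normal(spec.hpod_deg, spec.hpod_jitter_deg, size=n_ch))

    gain = np.exp(rng.normal(0.0, spec.gain_sd, size=n_ch))
    hbo_scale = np.ones(n_ch)
    hbr_scale = np.ones(n_ch)
    for e in spec.effects:
        if e.sex == sex:
            idx = np.array([c - 1 for c in e.channels])
            if e.chromophore == "HbO":
                hbo_scale[idx] *= e.scale
            else:
                hbr_scale[idx] *= e.scale

    comps = [
        (f_card, spec.cardiac_amp),
        (2 * f_card, spec.cardiac_amp * spec.harmonic_ratio),
        (f_resp, spec.respiratory_amp),
        (f_mayer, spec.mayer_amp),
    ]
    hbo = np.zeros((n, n_ch))
    hbr = np.zeros((n, n_ch))
    ratio = abs(spec.hbr_ratio)
    for f, amp in comps:
        phi0 = rng.uniform(0, 2 * np.pi)
        delta = _channel_phase_offsets(
            rng, m, spec.phase_dispersion_rad, spec.homotopic_coupling
        )
        # sin(2*pi*f*t + phi0 + delta_ch [- theta_ch]) via one complex outer
        # product instead of per-element transcendentals
        zt = np.exp(2j * np.pi * f * t)
        w = np.exp(1j * (phi0 + delta))
        osc = zt[:, None] * w[None, :]
        hbo += amp * gain * hbo_scale * osc.imag
        hbr += amp * ratio * gain * hbr_scale * (osc * np.exp(-1j * theta)).imag

    # slow drift: pink noise plus a gentle polynomial trend per channel
    hbo += spec.drift_sd * _pink_noise(rng, n, n_ch)
    hbr += spec.drift_sd * ratio * _pink_noise(rng, n, n_ch)
    x = np.linspace(-1, 1, n)
    poly = np.column_stack([x, x**2, x**3])
    hbo += poly @ (spec.drift_sd * 0.5 * rng.standard_normal((3, n_ch)))
    hbr += poly @ (spec.drift_sd * ratio * 0.5 * rng.standard_normal((3, n_ch)))

    clean_hbo = hbo.copy() if store_clean else None
    clean_hbr = hbr.copy() if store_clean else None

    if spec.noise_sd > 0:
        hbo = hbo + rng.normal(0, spec.noise_sd, size=(n, n_ch))
        hbr = hbr + rng.normal(0, spec.noise_sd * ratio, size=(n, n_ch))

    if spec.artifact_rate_per_min > 0 and spec.artifact_amp > 0:
        n_art = rng.poisson(spec.artifact_rate_per_min * spec.duration_s / 60.0)
        width = max(spec.artifact_width_s * spec.fs, 1.0)
        for _ in range(n_art):
            center = rng.uniform(0, n)
            amp = rng.exponential(spec.artifact_amp) * rng.choice([-1.0, 1.0])
            ch_gain = rng.uniform(0.5, 1.5, size=n_ch)
            bump = amp * np.exp(-0.5 * ((np.arange(n) - center) / width) ** 2)
            hbo += bump[:, None] * ch_gain
            hbr += bump[:, None] * ch_gain * ratio

    # forward modified Beer-Lambert: concentrations (umol/L) -> intensities
    conc = np.stack([hbo, hbr], axis=-1) * 1e-6  # mol/L
    dod = conc @ constants.pathlength_matrix().T
    intensities = np.exp(-dod)

    sid = f"sub-{'F' if sex == 'female' else 'M'}{subject_index:03d}"
    rec = RawIntensityRecording(sid, sex, spec.fs, intensities, montage=m)
    truth = GroundTruth(sid, sex, f_card, f_resp, np.rad2deg(theta) % 360.0,
                        hbo_scale, hbr_scale, clean_hbo, clean_hbr)
    return rec, truth


def iter_cohort(
    spec: CohortSpec,
    constants: OpticalConstants = DEFAULT_CONSTANTS,
    montage: Montage | None = None,
    store_clean: bool = False,
) -> Iterator[tuple[RawIntensityRecording, GroundTruth]]:
    """Stream the cohort one subject at a time (memory-friendly).

    Per-subject seeds are spawned deterministically from ``spec.seed``; females
    are enumerated first, then males.
    """
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_subjects)
    k = 0
    for i in range(spec.n_female):
        yield generate_subject(spec, i + 1, "female", children[k],
                               constants, montage, store_clean)
        k += 1
    for i in range(spec.n_male):
        yield generate_subject(spec, i + 1, "male", children[k],
                               constants, montage, store_clean)
        k += 1


def generate_cohort(
    spec: CohortSpec,
    constants: OpticalConstants = DEFAULT_CONSTANTS,
    montage: Montage | None = None,
    store_clean: bool = True,
) -> tuple[list[RawIntensityRecording], list[GroundTruth]]:
    """Materialize the full cohort (see :func:`iter_cohort` for streaming)."""
    recs, truths = [], []
    for rec, truth in iter_cohort(spec, constants, montage, store_clean):
        recs.append(rec)
        truths.append(truth)
    return recs, truths
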