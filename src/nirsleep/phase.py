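"""Hilbert-phase analysis: the hemoglobin phase-of-oxygenation-difference (hPod).

For each channel, the HbO and HbR series are mapped to analytic signals via the
Hilbert transform; the instantaneous phase difference phi_HbO(t) - phi_HbR(t)
is averaged over time (circularly) to give one angle per channel and subject,
expressed in degrees on [0, 360). Healthy hemodynamics put HbO and HbR close to
antiphase, so hPod concentrates near 180-210 degrees.

Instantaneous phase is only physically meaningful for narrowband signals, so
inputs are band-pass filtered (default 0.01-0.5 Hz, the respiratory/Mayer/
vasomotion range) before the transform; 5% of samples are trimmed at each edge
to suppress Hilbert end effects. Both constants are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .exceptions import (
    DataError,
    DimensionError,
    GroupingError,
    ParameterError,
)
from .preprocess import HemoSeries

__all__ = [
    "HPodResult",
    "instantaneous_phase",
    "hpod",
    "hpod_cohort",
    "hpod_histogram",
    "circular_mean_deg",
]

DEFAULT_BAND = (0.01, 0.5)
EDGE_TRIM_FRACTION = 0.05


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    """Circular mean of angles in degrees, mapped to [0, 360)."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    mean = np.arctan2(np.sin(a).mean(), np.cos(a).mean())
    return float(np.rad2deg(mean) % 360.0)


@dataclass(frozen=True)
class HPodResult:
    """Per-subject x per-channel hPod angles (degrees, [0, 360)).

    ``angles[s, c]`` is subject s's phase difference on retained channel c;
    ``subject_means`` are per-subject circular means across channels.
    """

    angles: np.ndarray
    subject_ids: tuple[str, ...]
    channel_ids: tuple[int, ...]
    sex: str | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, dtype=float)
        if a.ndim != 2:
            raise DimensionError("angles must be (subjects, channels)")
        if a.shape != (len(self.subject_ids), len(self.channel_ids)):
            raise DimensionError("angles shape does not match subject/channel ids")
        if np.any(a < 0) or np.any(a >= 360):
            raise DataError("angles must lie in [0, 360)")
        object.__setattr__(self, "angles", a)

    @property
    def subject_means(self) -> np.ndarray:
        return np.array([circular_mean_deg(row) for row in self.angles])

    @property
    def pooled(self) -> np.ndarray:
        return self.angles.ravel()

    @property
    def pooled_circular_mean(self) -> float:
        return circular_mean_deg(self.pooled)


def instantaneous_phase(x: np.ndarray, unwrap: bool = False) -> np.ndarray:
    """Argument of the analytic signal x + i*H[x], along axis 0.

    Raises on an identically-zero series, whose phase is undefined.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 8:
        raise ParameterError("need at least 8 samples")
    if not np.all(np.isfinite(x)):
        raise DataError("non-finite samples")
    flat = x.reshape(x.shape[0], -1)
    if np.any(np.all(flat == 0.0, axis=0)):
        raise DataError("phase undefined for an all-zero series")
    phase = np.angle(sps.hilbert(x, axis=0))
    if unwrap:
        phase = np.unwrap(phase, axis=0)
    return phase


def _bandpass(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    nyq = fs / 2
    if not (0 < lo < hi < nyq):
        raise ParameterError(f"invalid band {band} for fs={fs}")
    sos = sps.butter(3, [lo / nyq, hi / nyq], btype="band", output="sos")
    return sps.sosfiltfilt(sos, x, axis=0)


def hpod(
    hbo: np.ndarray,
    hbr: np.ndarray,
    fs: float | None = None,
    band: tuple[float, float] | None = DEFAULT_BAND,
    trim_fraction: float = EDGE_TRIM_FRACTION,
) -> float | np.ndarray:
    """Time-averaged HbO-HbR instantaneous-phase difference, degrees in [0, 360).

    The time average is a circular mean (mean resultant direction) of the
    wrapped phase-difference samples, after trimming ``trim_fraction`` of the
    samples at each edge. Band-pass filtering before the Hilbert transform is
    applied when ``fs`` and ``band`` are given; exact identities hpod(x, x) = 0
    and hpod(x, -x) = 180 hold regardless.

    Accepts 1-d series or (time, channel) arrays; returns a scalar or a
    per-channel vector accordingly.
    """
    hbo = np.asarray(hbo, dtype=float)
    hbr = np.asarray(hbr, dtype=float)
    if hbo.shape != hbr.shape:
        raise DimensionError(f"shape mismatch: {hbo.shape} vs {hbr.shape}")
    if not (0 <= trim_fraction < 0.5):
        raise ParameterError("trim_fraction must be in [0, 0.5)")
    if band is not None and fs is not None:
        hbo = _bandpass(hbo, fs, band)
        hbr = _bandpass(hbr, fs, band)
    d = instantaneous_phase(hbo) - instantaneous_phase(hbr)
    n = d.shape[0]
    k = int(np.floor(trim_fraction * n))
    if k:
        d = d[k:-k]
    mean = np.arctan2(np.sin(d).mean(axis=0), np.cos(d).mean(axis=0))
    deg = np.rad2deg(mean) % 360.0
    return float(deg) if deg.ndim == 0 else deg


def hpod_cohort(
    cohort: Sequence[HemoSeries],
    sex: str | None = None,
    channel_index: np.ndarray | None = None,
    channel_ids: Sequence[int] | None = None,
    band: tuple[float, float] | None = DEFAULT_BAND,
) -> HPodResult:
    """hPod for every subject of one sex on every (retained) channel."""
    sel = [h for h in cohort if sex is None or h.sex == sex]
    if not sel:
        raise GroupingError(f"no subjects with sex={sex!r}")
    rows = []
    for h in sel:
        hbo, hbr = h.hbo, h.hbr
        if hbo is None or hbr is None:
            raise DataError(f"subject {h.subject_id}: missing chromophore")
        if channel_index is not None:
            hbo = hbo[:, channel_index]
            hbr = hbr[:, channel_index]
        rows.append(hpod(hbo, hbr, fs=h.fs, band=band))
    angles = np.vstack(rows)
    ids = tuple(channel_ids) if channel_ids is not None else tuple(
        range(1, angles.shape[1] + 1)
    )
    return HPodResult(angles, tuple(h.subject_id for h in sel), ids, sex=sex)


def hpod_histogram(
    r: HPodResult, bin_width_deg: int = 30
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of pooled hPod angles on bins [k*w, (k+1)*w), w dividing 360.

    Returns (edges, counts); counts sum to the number of pooled angles. The
    same counts serve the standard and the polar (rose) rendering.
    """
    if bin_width_deg <= 0 or 360 % bin_width_deg != 0:
        raise ParameterError("bin width must be a positive divisor of 360")
    edges = np.arange(0, 360 + bin_width_deg, bin_width_deg, dtype=float)
    counts, _ = np.histogram(r.pooled, bins=edges)
    return edges, counts
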