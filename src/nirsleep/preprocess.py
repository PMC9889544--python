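"""Raw intensity -> optical density -> hemoglobin concentration preprocessing.

The chain implements the standard continuous-wave fNIRS pipeline:

1. **Optical density.** ``dOD(t, ch, lam) = -ln( I(t, ch, lam) / <I(., ch, lam)>_t )``
   using each channel's temporal mean intensity as the reference baseline. Scattering
   losses are time-invariant and cancel in this differential form.
2. **Wavelet motion-artifact suppression.** Per-series discrete wavelet decomposition;
   detail coefficients that are outliers under an interquartile-range rule are zeroed
   before reconstruction (spikes live in sparse large detail coefficients, the
   oscillatory physiology does not).
3. **Modified Beer-Lambert inversion.** For each time point and channel the 2x2 system

       dOD(lam_i) = D(lam_i) * x * [eps_HbO(lam_i), eps_HbR(lam_i)] . [dHbO, dHbR]

   is solved exactly for the chromophore concentration changes (umol/L), where D is
   the differential path-length factor and x the source-detector separation.
4. **Nuisance regression.** Least-squares removal of slow drift (Legendre polynomials
   orders 0..K on time rescaled to [-1, 1]), sinusoids at discrete Fourier frequencies
   inside configured physiological-noise bands at/above a cutoff, and optionally the
   across-channel mean ("global") signal.

Each step is exposed both as an sklearn-style transformer (composable in an
``sklearn.pipeline.Pipeline``) and as a module-level function operating on the
domain containers below.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import pywt
from numpy.polynomial import legendre as npleg
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import (
    CollinearityError,
    ConditioningError,
    DataError,
    DimensionError,
    DomainError,
    ParameterError,
)

__all__ = [
    "OpticalConstants",
    "DEFAULT_CONSTANTS",
    "RawIntensityRecording",
    "ODSeries",
    "HemoSeries",
    "OpticalDensity",
    "WaveletArtifactRemover",
    "BeerLambertInverter",
    "NuisanceRegressor",
    "intensity_to_od",
    "wavelet_denoise",
    "od_to_hemo",
    "nuisance_regress",
    "compute_hbt",
    "make_preprocessing_pipeline",
    "preprocess_recording",
]


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OpticalConstants:
    """Wavelengths, path-length factors, separation, and extinction matrix.

    ``extinction[i] = (eps_HbO(lam_i), eps_HbR(lam_i))`` in cm^-1 (mol/L)^-1.
    Defaults use 760/850 nm, DPF (5.3, 4.2) for the 4-month-old head, a 3.0 cm
    source-detector separation, and standard tabulated extinction values.
    """

    wavelengths: tuple[float, float] = (760.0, 850.0)
    dpf: tuple[float, float] = (5.3, 4.2)
    distance: float = 3.0
    extinction: tuple[tuple[float, float], tuple[float, float]] = (
        (1486.6, 3843.7),
        (2526.4, 1798.6),
    )

    def __post_init__(self) -> None:
        if not all(d > 0 for d in self.dpf):
            raise ParameterError("dpf entries must be positive")
        if self.distance <= 0:
            raise ParameterError("source-detector distance must be positive")
        E = np.asarray(self.extinction, dtype=float)
        if E.shape != (2, 2) or not np.all(np.isfinite(E)):
            raise ParameterError("extinction must be a finite 2x2 matrix")
        if np.linalg.cond(self.pathlength_matrix()) > 1e8:
            raise ConditioningError("extinction matrix is singular or near-singular")

    def pathlength_matrix(self) -> np.ndarray:
        """M = diag(D(lam) * x) @ E, so that dOD = M @ [dHbO, dHbR] (mol/L)."""
        E = np.asarray(self.extinction, dtype=float)
        return np.diag(np.asarray(self.dpf) * self.distance) @ E


DEFAULT_CONSTANTS = OpticalConstants()


def _check_time_channel(a: np.ndarray, name: str, ndim: int) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != ndim:
        raise DimensionError(f"{name}: expected {ndim}-d array, got {a.ndim}-d")
    return a


@dataclass(frozen=True)
class RawIntensityRecording:
    """Detected dual-wavelength light intensities for one subject.

    ``intensities`` has shape (time, channel, wavelength) with strictly
    positive arbitrary units.
    """

    subject_id: str
    sex: str  # "female" | "male"
    fs: float
    intensities: np.ndarray
    montage: object | None = None

    def __post_init__(self) -> None:
        arr = _check_time_channel(self.intensities, "intensities", 3)
        object.__setattr__(self, "intensities", arr)
        if self.sex not in ("female", "male"):
            raise DataError(f"unknown sex label {self.sex!r}")
        if self.fs <= 0:
            raise ParameterError("sampling rate must be positive")
        if not np.all(np.isfinite(arr)):
            raise DataError(f"subject {self.subject_id}: non-finite intensities")
        if np.any(arr <= 0):
            t, c, w = np.unravel_index(int(np.argmin(arr)), arr.shape)
            raise DomainError(
                f"subject {self.subject_id}: non-positive intensity at "
                f"sample {t}, channel {c + 1}, wavelength index {w}"
            )

    @property
    def duration_s(self) -> float:
        return self.intensities.shape[0] / self.fs

    def validate_duration(self, min_duration_s: float = 540.0) -> "RawIntensityRecording":
        if self.duration_s < min_duration_s:
            raise DataError(
                f"subject {self.subject_id}: duration {self.duration_s:.1f} s "
                f"< required {min_duration_s:.1f} s"
            )
        return self


@dataclass(frozen=True)
class ODSeries:
    """Optical-density changes, same (time, channel, wavelength) indexing as the
    raw recording; unitless; temporal mean ~ 0 when the baseline is the mean."""

    subject_id: str
    sex: str
    fs: float
    values: np.ndarray
    baseline: str = "temporal_mean"
    montage: object | None = None

    def __post_init__(self) -> None:
        arr = _check_time_channel(self.values, "values", 3)
        object.__setattr__(self, "values", arr)
        if not np.all(np.isfinite(arr)):
            raise DataError(f"subject {self.subject_id}: non-finite OD values")


@dataclass(frozen=True)
class HemoSeries:
    """Chromophore concentration changes (umol/L), shape (time, channel).

    ``hbt`` is materialized as hbo + hbr at construction, so the total-
    hemoglobin identity holds by construction.
    """

    subject_id: str
    sex: str
    fs: float
    hbo: np.ndarray
    hbr: np.ndarray
    hbt: np.ndarray = field(default=None)  # type: ignore[assignment]
    montage: object | None = None

    def __post_init__(self) -> None:
        hbo = _check_time_channel(self.hbo, "hbo", 2)
        hbr = _check_time_channel(self.hbr, "hbr", 2)
        if hbo.shape != hbr.shape:
            raise DimensionError(f"hbo {hbo.shape} vs hbr {hbr.shape}")
        if not (np.all(np.isfinite(hbo)) and np.all(np.isfinite(hbr))):
            raise DataError(f"subject {self.subject_id}: non-finite concentrations")
        object.__setattr__(self, "hbo", hbo)
        object.__setattr__(self, "hbr", hbr)
        object.__setattr__(self, "hbt", hbo + hbr)

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[1]

    def chromophore(self, name: str) -> np.ndarray:
        try:
            return {"HbO": self.hbo, "HbR": self.hbr, "HbT": self.hbt}[name]
        except KeyError:
            raise DataError(f"unknown chromophore {name!r}") from None


def compute_hbt(hbo: np.ndarray, hbr: np.ndarray) -> np.ndarray:
    """Total-hemoglobin change: elementwise dHbT = dHbO + dHbR."""
    hbo = np.asarray(hbo, dtype=float)
    hbr = np.asarray(hbr, dtype=float)
    if hbo.shape != hbr.shape:
        raise DimensionError(f"shape mismatch: {hbo.shape} vs {hbr.shape}")
    return hbo + hbr


# ---------------------------------------------------------------------------
# transformers
# ---------------------------------------------------------------------------


class OpticalDensity(TransformerMixin, BaseEstimator):
    """Convert positive light intensities to optical-density changes.

    ``fit`` stores the per-channel temporal-mean baseline ``baseline_``;
    ``transform`` returns ``-ln(X / baseline_)``. Arrays may be (time, ...) with
    any trailing shape; the baseline is taken over axis 0.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if np.any(X <= 0):
            idx = np.unravel_index(int(np.argmin(X)), X.shape)
            raise DomainError(f"non-positive intensity at index {idx}")
        self.baseline_ = X.mean(axis=0)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if np.any(X <= 0):
            idx = np.unravel_index(int(np.argmin(X)), X.shape)
            raise DomainError(f"non-positive intensity at index {idx}")
        return -np.log(X / self.baseline_)

    def inverse_transform(self, X):
        return self.baseline_ * np.exp(-np.asarray(X, dtype=float))


class WaveletArtifactRemover(TransformerMixin, BaseEstimator):
    """Suppress sparse motion spikes by zeroing outlier wavelet detail coefficients.

    Parameters
    ----------
    wavelet : orthogonal wavelet name (default "db4")
    level : decomposition depth (series must be at least 2**level samples)
    rule : "iqr" zeroes detail coefficients farther than ``iqr_factor`` IQRs from
        the per-level median; "none" reconstructs untouched (identity up to
        floating error).
    """

    def __init__(self, wavelet: str = "db4", level: int = 5, rule: str = "iqr",
                 iqr_factor: float = 1.5):
        self.wavelet = wavelet
        self.level = level
        self.rule = rule
        self.iqr_factor = iqr_factor

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if self.rule not in ("none", "iqr"):
            raise ParameterError(f"unknown threshold rule {self.rule!r}")
        n = X.shape[0]
        if n < 2 ** self.level:
            raise ParameterError(
                f"series of length {n} too short for {self.level} wavelet levels"
            )
        shape = X.shape
        flat = X.reshape(n, -1)
        coeffs = pywt.wavedec(flat, self.wavelet, level=self.level, axis=0)
        if self.rule == "iqr":
            for d in coeffs[1:]:  # detail levels only
                q1, med, q3 = np.percentile(d, [25.0, 50.0, 75.0], axis=0)
                lim = self.iqr_factor * (q3 - q1)
                out = np.abs(d - med) > lim
                d[out] = 0.0
        rec = pywt.waverec(coeffs, self.wavelet, axis=0)[:n]
        return rec.reshape(shape)


class BeerLambertInverter(TransformerMixin, BaseEstimator):
    """Invert the modified Beer-Lambert law.

    transform: (time, channel, 2) optical densities -> (time, channel, 2)
    concentration changes (dHbO, dHbR) in umol/L. ``inverse_transform`` applies
    the forward model, so the round trip is exact to machine precision.
    """

    def __init__(self, constants: OpticalConstants = DEFAULT_CONSTANTS):
        self.constants = constants

    def fit(self, X=None, y=None):
        M = self.constants.pathlength_matrix()
        if np.linalg.cond(M) > 1e8:
            raise ConditioningError("path-length matrix is near-singular")
        self.forward_matrix_ = M
        self.inverse_matrix_ = np.linalg.inv(M)
        return self

    def transform(self, X):
        if not hasattr(self, "inverse_matrix_"):
            self.fit()
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != 2:
            raise DimensionError("expected two wavelengths on the last axis")
        return X @ self.inverse_matrix_.T * 1e6  # mol/L -> umol/L

    def inverse_transform(self, X):
        if not hasattr(self, "forward_matrix_"):
            self.fit()
        X = np.asarray(X, dtype=float)
        return (X * 1e-6) @ self.forward_matrix_.T


class NuisanceRegressor(TransformerMixin, BaseEstimator):
    """Least-squares removal of drift, physiological sinusoids and global signal.

    The design matrix holds Legendre polynomials of order 0..``legendre_max_order``
    on time rescaled to [-1, 1], sine/cosine pairs at the discrete Fourier
    frequencies ( k / duration ) that fall inside ``bands`` and at/above
    ``cutoff_hz``, and optionally the across-channel mean series of the input.

    ``frequency_mode="bands"`` (default) places regressors only inside the
    configured physiological-noise bands; ``"all"`` uses every Fourier frequency
    at/above the cutoff, which projects out essentially the whole spectrum above
    the cutoff and should be considered aggressive.

    transform accepts (time, channel) or (time, channel, k) arrays; the global
    mean regressor and the residuals are computed per trailing slice.
    """

    def __init__(
        self,
        fs: float = 15.625,
        cutoff_hz: float = 0.09,
        legendre_max_order: int = 4,
        include_global_mean: bool = True,
        frequency_mode: str = "bands",
        bands: tuple[tuple[float, float], ...] = ((1.5, 2.5), (3.5, 4.5)),
    ):
        self.fs = fs
        self.cutoff_hz = cutoff_hz
        self.legendre_max_order = legendre_max_order
        self.include_global_mean = include_global_mean
        self.frequency_mode = frequency_mode
        self.bands = bands

    def _design(self, n: int) -> tuple[np.ndarray, list[str]]:
        if self.cutoff_hz >= self.fs / 2:
            raise ParameterError("cutoff must lie below the Nyquist frequency")
        t = np.arange(n) / self.fs
        dur = n / self.fs
        cols: list[np.ndarray] = []
        names: list[str] = []
        x = np.linspace(-1.0, 1.0, n)
        for k in range(self.legendre_max_order + 1):
            cols.append(npleg.legvander(x, k)[:, -1])
            names.append(f"legendre_{k}")
        freqs = np.arange(1, n // 2 + 1) / dur
        if self.frequency_mode == "all":
            sel = freqs >= self.cutoff_hz
        elif self.frequency_mode == "bands":
            sel = np.zeros_like(freqs, dtype=bool)
            for lo, hi in self.bands:
                sel |= (freqs >= lo) & (freqs <= hi)
            sel &= freqs >= self.cutoff_hz
        else:
            raise ParameterError(f"unknown frequency_mode {self.frequency_mode!r}")
        for f in freqs[sel]:
            cols.append(np.sin(2 * np.pi * f * t))
            cols.append(np.cos(2 * np.pi * f * t))
            names.append(f"sin_{f:.6g}Hz")
            names.append(f"cos_{f:.6g}Hz")
        return np.column_stack(cols), names

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ParameterError("need at least two time points")
        self.design_, self.design_names_ = self._design(X.shape[0])
        rank = np.linalg.matrix_rank(self.design_)
        if rank < self.design_.shape[1]:
            # name the columns implicated in the deficiency via pivoted QR
            from scipy.linalg import qr as sqr

            _, _, piv = sqr(self.design_, mode="economic", pivoting=True)
            bad = sorted(self.design_names_[j] for j in piv[rank:])
            raise CollinearityError(f"rank-deficient design; offending columns: {bad}")
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if not hasattr(self, "design_"):
            self.fit(X)
        if self.design_.shape[0] != X.shape[0]:
            self.fit(X)
        shape = X.shape
        out = np.empty_like(X, dtype=float)
        slices = X.reshape(shape[0], shape[1], -1) if X.ndim == 3 else X[..., None]
        res = np.empty_like(slices, dtype=float)
        for k in range(slices.shape[2]):
            xk = slices[:, :, k]
            design = self.design_
            if self.include_global_mean:
                g = xk.mean(axis=1, keepdims=True)
                design = np.column_stack([design, g])
            beta, *_ = np.linalg.lstsq(design, xk, rcond=None)
            res[:, :, k] = xk - design @ beta
        out = res.reshape(shape)
        return out


# ---------------------------------------------------------------------------
# functional wrappers on the domain containers
# ---------------------------------------------------------------------------


def intensity_to_od(rec: RawIntensityRecording) -> ODSeries:
    """Optical-density changes relative to each channel's temporal mean intensity."""
    vals = OpticalDensity().fit_transform(rec.intensities)
    return ODSeries(rec.subject_id, rec.sex, rec.fs, vals, montage=rec.montage)


def wavelet_denoise(
    od: ODSeries,
    wavelet: str = "db4",
    level: int = 5,
    rule: str = "iqr",
    iqr_factor: float = 1.5,
) -> ODSeries:
    """Wavelet motion-artifact suppression of every channel/wavelength series."""
    tr = WaveletArtifactRemover(wavelet, level, rule, iqr_factor)
    return replace(od, values=tr.fit_transform(od.values))


def od_to_hemo(od: ODSeries, constants: OpticalConstants = DEFAULT_CONSTANTS) -> HemoSeries:
    """Solve the 2x2 modified Beer-Lambert system per time point and channel."""
    conc = BeerLambertInverter(constants).fit().transform(od.values)
    return HemoSeries(od.subject_id, od.sex, od.fs,
                      hbo=conc[:, :, 0], hbr=conc[:, :, 1], montage=od.montage)


def nuisance_regress(
    h: HemoSeries,
    cutoff_hz: float = 0.09,
    legendre_max_order: int = 4,
    include_global_mean: bool = True,
    frequency_mode: str = "bands",
    bands: tuple[tuple[float, float], ...] = ((1.5, 2.5), (3.5, 4.5)),
    channel_mask: np.ndarray | None = None,
) -> HemoSeries:
    """Regress drift / physiological sinusoids / global mean out of each chromophore.

    ``channel_mask`` restricts which channels contribute to the global-mean
    regressor (e.g. the montage's retained channels); residuals are still
    returned for every channel.
    """
    reg = NuisanceRegressor(h.fs, cutoff_hz, legendre_max_order,
                            include_global_mean=False,
                            frequency_mode=frequency_mode, bands=bands)
    reg.fit(h.hbo)

    def _clean(x: np.ndarray) -> np.ndarray:
        design = reg.design_
        if include_global_mean:
            g = (x[:, channel_mask] if channel_mask is not None else x).mean(axis=1)
            design = np.column_stack([design, g])
        beta, *_ = np.linalg.lstsq(design, x, rcond=None)
        return x - design @ beta

    return replace(h, hbo=_clean(h.hbo), hbr=_clean(h.hbr))


def make_preprocessing_pipeline(
    constants: OpticalConstants = DEFAULT_CONSTANTS,
    denoise: bool = True,
    wavelet: str = "db4",
    level: int = 5,
    rule: str = "iqr",
) -> "Pipeline":
    """sklearn Pipeline: intensities (T, C, 2) -> concentration changes (T, C, 2)."""
    from sklearn.pipeline import Pipeline

    steps = [("od", OpticalDensity())]
    if denoise:
        steps.append(("wavelet", WaveletArtifactRemover(wavelet, level, rule)))
    steps.append(("beer_lambert", BeerLambertInverter(constants)))
    return Pipeline(steps)


def preprocess_recording(
    rec: RawIntensityRecording,
    constants: OpticalConstants = DEFAULT_CONSTANTS,
    denoise: bool = True,
    **wavelet_kw,
) -> HemoSeries:
    """Raw intensities -> HemoSeries via OD conversion, optional wavelet
    denoising, and Beer-Lambert inversion (no nuisance regression)."""
    od = intensity_to_od(rec)
    if denoise:
        od = wavelet_denoise(od, **wavelet_kw)
    return od_to_hemo(od, constants)
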