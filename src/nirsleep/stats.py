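"""Group significance testing: channel-wise PSD differences and the hPod test.

Two channel-wise modes are provided.

``paired-over-frequency`` (default): for each channel, the two sexes' group-
mean log10-PSD curves are compared by a paired t-test across the frequency bins
of the analysis band. This mirrors an analysis in which "PSD data" of the two
groups are paired bin-by-bin; it treats bins as the sampling unit and therefore
inherits their correlation.

``band-power``: for each channel, each subject's log10 band-integrated power is
the sampling unit, compared across sexes by Welch's unequal-variance two-sample
t-test. This is the statistically conventional subject-level test and is the
one whose type-I error is calibrated at alpha under the null.

No multiple-comparison correction is applied by default (raw p < alpha across
the retained channels); Benjamini-Hochberg adjustment is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as spstats

from .exceptions import (
    DimensionError,
    GroupingError,
    ParameterError,
    SampleSizeError,
)
from .phase import HPodResult
from .preprocess import HemoSeries
from .spectral import compute_psd

__all__ = [
    "ChannelTestResult",
    "channelwise_psd_test",
    "hpod_group_test",
    "significant_channels",
    "replicate_median_significance",
    "subject_channel_psds",
]

ANALYSIS_BAND = (0.0, 4.5)


@dataclass(frozen=True)
class ChannelTestResult:
    """t statistic and p-value of the sex comparison for one channel."""

    channel: int
    t: float
    p: float
    kind: str
    chromophore: str

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ParameterError("p-value outside [0, 1]")

    def significant(self, alpha: float = 0.05) -> bool:
        return bool(self.p < alpha)


def subject_channel_psds(
    cohort: Sequence[HemoSeries],
    chromophore: str,
    channel_index: np.ndarray | None = None,
    nperseg: int | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Welch PSD per subject and channel on a common grid.

    Returns (freqs, psd[subject, freq, channel], sexes). The Welch segment is
    capped at the shortest recording so all subjects share one grid.
    """
    if not cohort:
        raise GroupingError("empty cohort")
    nmin = min(h.hbo.shape[0] for h in cohort)
    if nperseg is None:
        nperseg = min(int(round(60.0 * cohort[0].fs)), nmin)
    freqs = None
    out = []
    sexes = []
    for h in cohort:
        x = h.chromophore(chromophore)
        if channel_index is not None:
            x = x[:, channel_index]
        res = compute_psd(x, h.fs, method="welch", nperseg=nperseg)
        if freqs is None:
            freqs = res.freqs
        elif res.freqs.shape != freqs.shape or not np.allclose(res.freqs, freqs):
            raise DimensionError("subjects yield different PSD grids")
        out.append(res.power)
        sexes.append(h.sex)
    return freqs, np.stack(out), sexes


def _split_by_sex(psds: np.ndarray, sexes: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    sexes = np.asarray(sexes)
    f = psds[sexes == "female"]
    m = psds[sexes == "male"]
    if len(f) == 0 or len(m) == 0:
        raise GroupingError("both sexes must be represented")
    return f, m


def channelwise_psd_test(
    cohort: Sequence[HemoSeries],
    chromophore: str = "HbO",
    alpha: float = 0.05,
    mode: str = "paired-over-frequency",
    band: tuple[float, float] = ANALYSIS_BAND,
    channel_index: np.ndarray | None = None,
    channel_ids: Sequence[int] | None = None,
    nperseg: int | None = None,
) -> list[ChannelTestResult]:
    """Per-channel test of female-vs-male PSD difference (see module docstring)."""
    freqs, psds, sexes = subject_channel_psds(cohort, chromophore, channel_index, nperseg)
    fem, mal = _split_by_sex(psds, sexes)
    sel = (freqs >= band[0]) & (freqs <= band[1]) & (freqs > 0)
    if not np.any(sel):
        raise ParameterError("analysis band contains no frequency bins")
    n_ch = psds.shape[2]
    ids = list(channel_ids) if channel_ids is not None else list(range(1, n_ch + 1))
    if len(ids) != n_ch:
        raise DimensionError("channel_ids length mismatch")
    eps = 1e-20 * float(psds.max())
    results = []
    for c in range(n_ch):
        if mode == "paired-over-frequency":
            a = np.log10(mal[:, sel, c].mean(axis=0) + eps)
            b = np.log10(fem[:, sel, c].mean(axis=0) + eps)
            d = a - b
            if np.allclose(d, 0.0):
                t, p = 0.0, 1.0
            else:
                t, p = spstats.ttest_rel(a, b)
        elif mode == "band-power":
            df = freqs[1] - freqs[0]
            pa = np.log10(mal[:, sel, c].sum(axis=1) * df + eps)
            pb = np.log10(fem[:, sel, c].sum(axis=1) * df + eps)
            t, p = spstats.ttest_ind(pa, pb, equal_var=False)
        else:
            raise ParameterError(f"unknown test mode {mode!r}")
        results.append(ChannelTestResult(ids[c], float(t), float(p), mode, chromophore))
    return results


def significant_channels(
    results: Sequence[ChannelTestResult],
    alpha: float = 0.05,
    method: str | None = None,
) -> list[int]:
    """Channel ids with p < alpha, ascending; ``method="fdr_bh"`` applies
    Benjamini-Hochberg adjustment before thresholding."""
    ps = np.array([r.p for r in results])
    if method == "fdr_bh":
        ps = spstats.false_discovery_control(ps, method="bh")
    elif method is not None:
        raise ParameterError(f"unknown adjustment {method!r}")
    return sorted(r.channel for r, p in zip(results, ps) if p < alpha)


def replicate_median_significance(
    replicate_results: Sequence[Sequence[ChannelTestResult]],
    alpha: float = 0.05,
) -> list[int]:
    """Channels significant in the *median* replicate.

    For each channel, take the median p-value across replicate cohorts and
    threshold at alpha. Channels carrying a real effect have median p near 0;
    null channels have median p near 0.5, so this aggregate recovers exactly
    the effect set once per-replicate power is high.
    """
    if not replicate_results:
        raise SampleSizeError("need at least one replicate")
    by_channel: dict[int, list[float]] = {}
    for rep in replicate_results:
        for r in rep:
            by_channel.setdefault(r.channel, []).append(r.p)
    counts = {len(v) for v in by_channel.values()}
    if len(counts) != 1:
        raise DimensionError("replicates cover different channel sets")
    return sorted(c for c, ps in by_channel.items() if np.median(ps) < alpha)


def hpod_group_test(
    r_female: HPodResult, r_male: HPodResult
) -> tuple[float, float]:
    """Welch two-sample t-test on subject-level mean hPod angles.

    Angles are compared on the branch [0, 360) centered at 180 degrees (the
    physiological antiphase), so values around 180-210 never wrap. Returns
    (t, p); identical groups give t = 0.
    """
    a = r_female.subject_means
    b = r_male.subject_means
    if len(a) < 2 or len(b) < 2:
        raise SampleSizeError("need at least 2 subjects per group")
    # branch [0, 360): farthest from the 180-degree center, so no wrap there
    a = np.asarray(a) % 360.0
    b = np.asarray(b) % 360.0
    if np.allclose(a.var(), 0) and np.allclose(b.var(), 0) and np.allclose(
        a.mean(), b.mean()
    ):
        return 0.0, 1.0
    t, p = spstats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
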