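"""Functional-connectivity adjacency matrices from channel-pairwise Pearson r.

Same-chromophore matrices (HbO x HbO, HbR x HbR, HbT x HbT) are symmetric with
unit diagonal. The HbO x HbR cross matrix is generally asymmetric and its
diagonal — the correlation of a channel's own HbO and HbR series — is expected
to be negative for physiological signals, since the two chromophores oscillate
near antiphase.

Group averaging applies Fisher's z transform entrywise before the mean and
transforms back, which removes the bias of averaging bounded correlations;
plain averaging is available. Channels with zero variance are marked invalid
rather than propagating NaN, and are excluded from strength summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import (
    ChromophoreError,
    DataError,
    GroupingError,
    PairingError,
)
from .montage import Montage, homotopic_pairs
from .preprocess import HemoSeries

__all__ = [
    "FCMatrix",
    "fc_matrix",
    "group_mean_fc",
    "connectivity_strength",
    "homotopic_profile",
]

_PAIRS = {"HbO", "HbR", "HbT"}


@dataclass(frozen=True)
class FCMatrix:
    """Channel x channel correlation matrix for one chromophore pair.

    ``valid[i]`` is False for channels whose series had zero variance; their
    rows/columns are set to 0 and flagged, never NaN.
    """

    matrix: np.ndarray
    pair: tuple[str, str]
    channel_ids: tuple[int, ...]
    valid: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise DataError("FC matrix must be square")
        if m.shape[0] != len(self.channel_ids):
            raise DataError("channel_ids length must match matrix size")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "valid", np.asarray(self.valid, dtype=bool))

    @property
    def is_cross(self) -> bool:
        return self.pair[0] != self.pair[1]

    def index_of(self, cid: int) -> int:
        try:
            return self.channel_ids.index(cid)
        except ValueError:
            raise PairingError(f"channel {cid} not present in FC matrix") from None


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    ok = sd > 0
    z = np.zeros_like(x)
    z[:, ok] = x[:, ok] / sd[ok]
    return z, ok


def fc_matrix(
    h: HemoSeries,
    pair: tuple[str, str] = ("HbO", "HbO"),
    channel_index: np.ndarray | None = None,
    channel_ids: Sequence[int] | None = None,
) -> FCMatrix:
    """Pearson-correlation adjacency matrix between channel time courses.

    Entry (m, n) is corr(pair[0] series of channel m, pair[1] series of
    channel n). ``channel_index`` selects columns (e.g. retained channels);
    ``channel_ids`` supplies their 1-based ids for labeling.
    """
    a, b = pair
    if a not in _PAIRS or b not in _PAIRS:
        raise ChromophoreError(f"unknown chromophore pair {pair}")
    xa = h.chromophore(a)
    xb = h.chromophore(b)
    if channel_index is not None:
        xa = xa[:, channel_index]
        xb = xb[:, channel_index]
    if xa.shape[0] < 3:
        raise DataError("need at least 3 time points for a correlation")
    n = xa.shape[1]
    za, oka = _standardize(xa)
    zb, okb = _standardize(xb)
    r = za.T @ zb / xa.shape[0]
    np.clip(r, -1.0, 1.0, out=r)
    valid = oka & okb
    r[~valid, :] = 0.0
    r[:, ~valid] = 0.0
    if a == b:
        r = 0.5 * (r + r.T)
        np.fill_diagonal(r, np.where(valid, 1.0, 0.0))
    ids = tuple(channel_ids) if channel_ids is not None else tuple(range(1, n + 1))
    return FCMatrix(r, (a, b), ids, valid, label=h.subject_id)


def group_mean_fc(
    cohort: Sequence[HemoSeries],
    sex: str | None,
    pair: tuple[str, str] = ("HbO", "HbO"),
    fisher: bool = True,
    channel_index: np.ndarray | None = None,
    channel_ids: Sequence[int] | None = None,
) -> FCMatrix:
    """Elementwise group average of subject FC matrices.

    With ``fisher=True`` entries are atanh-transformed before the mean and
    tanh-transformed back; the unit diagonal of same-chromophore matrices is
    preserved exactly. A single-subject group returns that subject's matrix.
    """
    sel = [h for h in cohort if sex is None or h.sex == sex]
    if not sel:
        raise GroupingError(f"no subjects with sex={sex!r}")
    mats = [fc_matrix(h, pair, channel_index, channel_ids) for h in sel]
    valid = np.logical_and.reduce([m.valid for m in mats])
    stack = np.stack([m.matrix for m in mats])
    if fisher:
        z = np.arctanh(np.clip(stack, -1 + 1e-12, 1 - 1e-12))
        mean = np.tanh(z.mean(axis=0))
    else:
        mean = stack.mean(axis=0)
    if pair[0] == pair[1]:
        np.fill_diagonal(mean, np.where(valid, 1.0, 0.0))
    label = f"{pair[0]}x{pair[1]}/{sex or 'all'}"
    return FCMatrix(mean, pair, mats[0].channel_ids, valid, label=label)


def connectivity_strength(fc: FCMatrix) -> np.ndarray:
    """Per-channel mean of off-diagonal correlations in the channel's row.

    Only defined for same-chromophore (symmetric) matrices; invalid channels
    are excluded from each row's mean and get NaN-free strength 0.
    """
    if fc.is_cross:
        raise ChromophoreError("connectivity strength needs a same-chromophore matrix")
    n = fc.matrix.shape[0]
    out = np.zeros(n)
    for i in range(n):
        mask = fc.valid.copy()
        mask[i] = False
        if fc.valid[i] and mask.any():
            out[i] = fc.matrix[i, mask].mean()
    return out


def homotopic_profile(fc: FCMatrix, m: Montage) -> list[tuple[tuple[int, int], float]]:
    """Correlation at each homotopic (i, i + offset) pair present in the matrix.

    Returns ``[((i, j), r), ...]`` for every pair whose two channels are both
    in the matrix's channel set.
    """
    pairs = homotopic_pairs(m)
    present = set(fc.channel_ids)
    out = []
    for i, j in pairs:
        if i in present and j in present:
            out.append(((i, j), float(fc.matrix[fc.index_of(i), fc.index_of(j)])))
    if not out:
        raise PairingError("no homotopic pair is present in the FC matrix")
    return out
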