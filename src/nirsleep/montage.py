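"""Probe geometry for the 16-source / 24-detector infant cap.

A *montage* describes the optode layout and the measurement channels defined by
adjacent source-detector pairs. The default montage carries 52 channels; six
occipital channels (whose source or detector sits where the sleeping infant's
head rests against the parent) are flagged and excluded, leaving 46 analyzed
channels that use 14 sources and 19 detectors. Channels are numbered 1..52 with
left-hemisphere channels 1..26 and their right-hemisphere homotopic partners at
an id offset of 26, so the homotopic pairs are (1, 27), (2, 28), ..., (26, 52).

Positions are normalized 2-D coordinates in [0, 1]^2, a planar projection of
10-20 cap placement; they are approximate and intended for topographic display,
not scalp registration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .exceptions import DimensionError, PairingError, StructuralError

SOURCE = "source"
DETECTOR = "detector"

__all__ = [
    "Optode",
    "Channel",
    "Montage",
    "load_montage",
    "default_montage",
    "retained_channels",
    "homotopic_pairs",
    "topographic_map",
]


@dataclass(frozen=True)
class Optode:
    """A light source or detector with a planar position."""

    id: int
    kind: str  # "source" or "detector"
    position: tuple[float, float]
    occipital: bool = False

    def __post_init__(self) -> None:
        if self.kind not in (SOURCE, DETECTOR):
            raise StructuralError(f"optode {self.id}: unknown kind {self.kind!r}")
        if not np.all(np.isfinite(self.position)):
            raise StructuralError(f"optode {self.id}: non-finite position")


@dataclass(frozen=True)
class Channel:
    """A measurement channel formed by one source-detector pair.

    ``position`` is the midpoint of the optode pair; ``retained`` is True iff
    neither optode is flagged occipital.
    """

    id: int
    source_id: int
    detector_id: int
    position: tuple[float, float]
    retained: bool


class Montage:
    """Validated optode/channel layout.

    Parameters
    ----------
    optodes : iterable of Optode
    channel_defs : iterable of (channel_id, source_id, detector_id)
    homotopic_offset : int
        Id offset between left-hemisphere channels and their mirror partners.
    """

    def __init__(
        self,
        optodes: Iterable[Optode],
        channel_defs: Iterable[tuple[int, int, int]],
        homotopic_offset: int = 26,
    ) -> None:
        self.optodes: tuple[Optode, ...] = tuple(optodes)
        self.homotopic_offset = int(homotopic_offset)

        sources = {o.id: o for o in self.optodes if o.kind == SOURCE}
        detectors = {o.id: o for o in self.optodes if o.kind == DETECTOR}
        if len(sources) != sum(o.kind == SOURCE for o in self.optodes):
            raise StructuralError("duplicate source ids")
        if len(detectors) != sum(o.kind == DETECTOR for o in self.optodes):
            raise StructuralError("duplicate detector ids")

        channels: list[Channel] = []
        seen_ids: set[int] = set()
        for cid, sid, did in channel_defs:
            if cid in seen_ids:
                raise StructuralError(f"duplicate channel id {cid}")
            seen_ids.add(cid)
            if sid not in sources:
                raise StructuralError(f"channel {cid}: undeclared source {sid}")
            if did not in detectors:
                raise StructuralError(f"channel {cid}: undeclared detector {did}")
            src, det = sources[sid], detectors[did]
            pos = (
                0.5 * (src.position[0] + det.position[0]),
                0.5 * (src.position[1] + det.position[1]),
            )
            channels.append(
                Channel(cid, sid, did, pos, retained=not (src.occipital or det.occipital))
            )
        channels.sort(key=lambda c: c.id)
        self.channels: tuple[Channel, ...] = tuple(channels)
        self._sources = sources
        self._detectors = detectors

    # -- counts ------------------------------------------------------------
    @property
    def n_sources(self) -> int:
        return len(self._sources)

    @property
    def n_detectors(self) -> int:
        return len(self._detectors)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_retained(self) -> int:
        return sum(c.retained for c in self.channels)

    @property
    def retained_sources(self) -> set[int]:
        return {c.source_id for c in self.channels if c.retained}

    @property
    def retained_detectors(self) -> set[int]:
        return {c.detector_id for c in self.channels if c.retained}

    def channel(self, cid: int) -> Channel:
        for c in self.channels:
            if c.id == cid:
                return c
        raise KeyError(cid)

    @property
    def retained_ids(self) -> list[int]:
        return [c.id for c in self.channels if c.retained]

    def retained_index(self) -> np.ndarray:
        """0-based positions of retained channels within the id-sorted channel list."""
        return np.array([i for i, c in enumerate(self.channels) if c.retained])

    # -- serialization -----------------------------------------------------
    def to_config(self) -> dict:
        return {
            "homotopic_offset": self.homotopic_offset,
            "optodes": [
                {
                    "id": o.id,
                    "kind": o.kind,
                    "position": list(o.position),
                    "occipital": o.occipital,
                }
                for o in self.optodes
            ],
            "channels": [
                {"id": c.id, "source": c.source_id, "detector": c.detector_id}
                for c in self.channels
            ],
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "Montage":
        try:
            optodes = [
                Optode(
                    int(o["id"]),
                    str(o["kind"]),
                    (float(o["position"][0]), float(o["position"][1])),
                    bool(o.get("occipital", False)),
                )
                for o in cfg["optodes"]
            ]
            chans = [
                (int(c["id"]), int(c["source"]), int(c["detector"]))
                for c in cfg["channels"]
            ]
        except (KeyError, TypeError, IndexError) as exc:
            raise StructuralError(f"malformed montage config: {exc}") from exc
        return cls(optodes, chans, int(cfg.get("homotopic_offset", 26)))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_config(), indent=1))


def load_montage(path: str | Path | None = None) -> Montage:
    """Load a montage from a JSON config; with ``path=None`` load the packaged
    default cap (52 channels, 46 retained)."""
    if path is None:
        text = resources.files("nirsleep").joinpath("data/default_montage.json").read_text()
    else:
        text = Path(path).read_text()
    return Montage.from_config(json.loads(text))


_DEFAULT: Montage | None = None


def default_montage() -> Montage:
    """The packaged 16-source / 24-detector infant cap (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_montage(None)
    return _DEFAULT


def retained_channels(m: Montage) -> list[Channel]:
    """Channels surviving the occipital exclusion, in ascending id order."""
    return [c for c in m.channels if c.retained]


def homotopic_pairs(m: Montage) -> list[tuple[int, int]]:
    """Mirror-symmetric channel-id pairs (i, i + offset) for i = 1..offset.

    Requires the montage's channel count to be exactly twice the homotopic
    offset (left block + mirrored right block).
    """
    off = m.homotopic_offset
    if m.n_channels != 2 * off:
        raise PairingError(
            f"cannot pair {m.n_channels} channels with homotopic offset {off}"
        )
    ids = sorted(c.id for c in m.channels)
    lo, hi = ids[:off], ids[off:]
    if hi != [i + off for i in lo]:
        raise PairingError("channel ids do not form two homotopic blocks")
    return [(i, i + off) for i in lo]


def topographic_map(
    values: Sequence[float],
    m: Montage,
    resolution: int = 64,
    power: float = 2.0,
) -> np.ndarray:
    """Interpolate per-channel scalars onto a ``resolution x resolution`` grid.

    Inverse-distance weighting (default power 2) from the retained channels'
    planar positions. The map is linear in ``values`` (fixed weights), and a
    single nonzero channel yields a grid maximum at its own position.

    Returns an array ``grid[iy, ix]`` over x, y in [0, 1].
    """
    chans = retained_channels(m)
    vals = np.asarray(values, dtype=float)
    if vals.shape != (len(chans),):
        raise DimensionError(
            f"expected {len(chans)} channel values, got shape {vals.shape}"
        )
    pos = np.array([c.position for c in chans])  # (C, 2)
    xs = np.linspace(0.0, 1.0, resolution)
    gx, gy = np.meshgrid(xs, xs)
    # squared distances grid-node -> channel
    d2 = (gx[..., None] - pos[:, 0]) ** 2 + (gy[..., None] - pos[:, 1]) ** 2
    with np.errstate(divide="ignore"):
        w = d2 ** (-power / 2.0)
    # exact hits: take the channel value itself
    hit = d2 < 1e-12
    w = np.where(np.isinf(w), 0.0, w)
    grid = (w * vals).sum(axis=-1) / np.maximum(w.sum(axis=-1), 1e-300)
    if hit.any():
        iy, ix, ic = np.nonzero(hit)
        grid[iy, ix] = vals[ic]
    return grid
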