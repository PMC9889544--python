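"""Cohort readers/writers, SNIRF interchange, run configuration and pipeline.

Subject disk layout (plain-text interchange format):

``<subject_id>.tsv``
    wide table, first column ``time_s``, then one column per channel and
    wavelength named ``chNN_wlK`` (NN = 1-based channel id, K = 1 or 2),
    holding raw detected intensities.
``<subject_id>.json``
    sidecar with ``subject_id``, ``sex``, ``fs``, ``n_channels``,
    ``n_wavelengths`` and optional ``montage`` reference.
``<subject_id>_truth.json``
    optional generator ground truth (scalars and per-channel vectors).

SNIRF (HDF5) read/write covers the subset needed for raw continuous-wave
recordings: ``/nirs/data1/dataTimeSeries`` with a measurement list, and
``/nirs/probe`` carrying 2-D optode positions, which converts to/from the
package's montage JSON (occipital flags are not part of SNIRF and must be
supplied separately when converting).

:func:`run_pipeline` drives the full analysis — simulate (or read) a cohort,
preprocess, and produce group activation maps, PSD curves with peak and shift
estimates, channel-wise tests, adjacency matrices, hPod histograms and the
hPod group test — writing a machine-readable JSON summary plus figures. Every
number that appears in a figure is also present in the summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .connectivity import connectivity_strength, group_mean_fc, homotopic_profile
from .exceptions import GroupingError, InputError, NirsError
from .montage import Montage, default_montage, load_montage, topographic_map
from .phase import hpod_cohort, hpod_histogram
from .preprocess import (
    DEFAULT_CONSTANTS,
    HemoSeries,
    OpticalConstants,
    RawIntensityRecording,
    nuisance_regress,
    preprocess_recording,
)
from .spectral import (
    PSDResult,
    estimate_frequency_shift,
    peak_frequency,
    smooth_log_psd,
)
from .stats import channelwise_psd_test, hpod_group_test, significant_channels
from .synthetic_data import CohortSpec, GroundTruth, iter_cohort

logger = logging.getLogger("nirsleep")

__all__ = [
    "write_subject",
    "read_subject",
    "write_cohort",
    "read_cohort",
    "write_snirf",
    "read_snirf",
    "montage_to_snirf_probe",
    "snirf_probe_to_montage",
    "RunConfig",
    "load_config",
    "run_pipeline",
]

DEFAULT_MIN_DURATION_S = 540.0


# ---------------------------------------------------------------------------
# TSV + JSON sidecar subject format
# ---------------------------------------------------------------------------


def _intensity_frame(rec: RawIntensityRecording) -> pd.DataFrame:
    t, c, w = rec.intensities.shape
    cols = {"time_s": np.arange(t) / rec.fs}
    for ch in range(c):
        for wl in range(w):
            cols[f"ch{ch + 1:02d}_wl{wl + 1}"] = rec.intensities[:, ch, wl]
    return pd.DataFrame(cols)


def write_subject(
    directory: str | Path,
    rec: RawIntensityRecording,
    truth: GroundTruth | None = None,
) -> Path:
    """Write one subject as TSV + JSON sidecar (+ optional ground truth)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tsv = directory / f"{rec.subject_id}.tsv"
    _intensity_frame(rec).to_csv(tsv, sep="\t", index=False)
    sidecar = {
        "subject_id": rec.subject_id,
        "sex": rec.sex,
        "fs": rec.fs,
        "n_channels": int(rec.intensities.shape[1]),
        "n_wavelengths": int(rec.intensities.shape[2]),
        "montage": "default",
    }
    (directory / f"{rec.subject_id}.json").write_text(json.dumps(sidecar, indent=1))
    if truth is not None:
        td = {
            "subject_id": truth.subject_id,
            "sex": truth.sex,
            "cardiac_hz": truth.cardiac_hz,
            "respiratory_hz": truth.respiratory_hz,
            "hpod_deg": [float(v) for v in truth.hpod_deg],
            "hbo_scale": [float(v) for v in truth.hbo_scale],
            "hbr_scale": [float(v) for v in truth.hbr_scale],
        }
        (directory / f"{rec.subject_id}_truth.json").write_text(json.dumps(td, indent=1))
    return tsv


def read_subject(
    sidecar_path: str | Path, min_duration_s: float = 0.0
) -> RawIntensityRecording:
    """Read one subject from its JSON sidecar (TSV expected alongside)."""
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    for key in ("subject_id", "sex", "fs"):
        if key not in meta:
            raise InputError(f"{sidecar_path.name}: missing {key!r} in sidecar")
    tsv = sidecar_path.with_suffix(".tsv")
    if not tsv.exists():
        raise InputError(f"{tsv} not found")
    frame = pd.read_csv(tsv, sep="\t", float_precision="round_trip")
    tcol = frame.pop("time_s").to_numpy()
    if len(tcol) > 1:
        dt = np.median(np.diff(tcol))
        if not np.isclose(dt, 1.0 / meta["fs"], rtol=1e-6):
            raise InputError(
                f"{tsv.name}: TSV row spacing {dt:.6g}s inconsistent with "
                f"sidecar fs={meta['fs']}"
            )
    n_ch = int(meta.get("n_channels", 0)) or max(
        int(c[2:4]) for c in frame.columns
    )
    n_wl = int(meta.get("n_wavelengths", 2))
    arr = np.empty((len(frame), n_ch, n_wl))
    for ch in range(n_ch):
        for wl in range(n_wl):
            arr[:, ch, wl] = frame[f"ch{ch + 1:02d}_wl{wl + 1}"].to_numpy()
    rec = RawIntensityRecording(meta["subject_id"], meta["sex"], float(meta["fs"]), arr)
    if min_duration_s > 0:
        rec.validate_duration(min_duration_s)
    return rec


def write_cohort(
    directory: str | Path,
    cohort: Iterable[tuple[RawIntensityRecording, GroundTruth | None]],
) -> Path:
    directory = Path(directory)
    for rec, truth in cohort:
        write_subject(directory, rec, truth)
    return directory


def read_cohort(
    directory: str | Path,
    strict: bool = False,
    min_duration_s: float = 0.0,
) -> list[RawIntensityRecording]:
    """Load every subject (TSV+sidecar and SNIRF) found in a directory.

    Malformed subjects are skipped with a logged warning unless ``strict``.
    """
    directory = Path(directory)
    sidecars = sorted(
        p for p in directory.glob("*.json")
        if not p.name.endswith("_truth.json") and p.with_suffix(".tsv").exists()
    )
    snirfs = sorted(directory.glob("*.snirf"))
    if not sidecars and not snirfs:
        raise InputError(f"no subjects found in {directory}")
    out: list[RawIntensityRecording] = []
    for path in sidecars:
        try:
            out.append(read_subject(path, min_duration_s))
        except NirsError as exc:
            if strict:
                raise
            logger.warning("skipping %s: %s", path.name, exc)
    for path in snirfs:
        try:
            rec = read_snirf(path)
            if min_duration_s > 0:
                rec.validate_duration(min_duration_s)
            out.append(rec)
        except NirsError as exc:
            if strict:
                raise
            logger.warning("skipping %s: %s", path.name, exc)
    if not out:
        raise InputError(f"no valid subjects in {directory}")
    return out


# ---------------------------------------------------------------------------
# SNIRF (HDF5) interchange
# ---------------------------------------------------------------------------


def montage_to_snirf_probe(m: Montage) -> dict:
    """SNIRF-style probe description arrays for a montage."""
    sources = sorted((o for o in m.optodes if o.kind == "source"), key=lambda o: o.id)
    dets = sorted((o for o in m.optodes if o.kind == "detector"), key=lambda o: o.id)
    return {
        "sourcePos2D": np.array([s.position for s in sources]),
        "detectorPos2D": np.array([d.position for d in dets]),
        "sourceLabels": [f"S{s.id}" for s in sources],
        "detectorLabels": [f"D{d.id}" for d in dets],
    }


def snirf_probe_to_montage(
    probe: dict,
    channel_defs: Sequence[tuple[int, int, int]],
    occipital_sources: Sequence[int] = (),
    occipital_detectors: Sequence[int] = (),
    homotopic_offset: int = 26,
) -> Montage:
    """Build a montage from SNIRF probe arrays plus the flags SNIRF lacks."""
    from .montage import Optode

    optodes = []
    for i, pos in enumerate(np.asarray(probe["sourcePos2D"]), start=1):
        optodes.append(Optode(i, "source", (float(pos[0]), float(pos[1])),
                              i in set(occipital_sources)))
    for i, pos in enumerate(np.asarray(probe["detectorPos2D"]), start=1):
        optodes.append(Optode(i, "detector", (float(pos[0]), float(pos[1])),
                              i in set(occipital_detectors)))
    return Montage(optodes, channel_defs, homotopic_offset)


def write_snirf(
    path: str | Path,
    rec: RawIntensityRecording,
    montage: Montage | None = None,
    wavelengths: tuple[float, float] = DEFAULT_CONSTANTS.wavelengths,
) -> Path:
    """Write a raw continuous-wave recording as a SNIRF (HDF5) file."""
    import h5py

    m = montage or (rec.montage if isinstance(rec.montage, Montage) else default_montage())
    t, n_ch, n_wl = rec.intensities.shape
    flat = rec.intensities.reshape(t, n_ch * n_wl)
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("/nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=rec.subject_id)
        meta.create_dataset("sex", data=rec.sex)
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="cm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries", data=flat)
        data.create_dataset("time", data=np.arange(t) / rec.fs)
        k = 0
        for ch in range(n_ch):
            chan = m.channels[ch]
            for wl in range(n_wl):
                ml = data.create_group(f"measurementList{k + 1}")
                ml.create_dataset("sourceIndex", data=int(chan.source_id))
                ml.create_dataset("detectorIndex", data=int(chan.detector_id))
                ml.create_dataset("wavelengthIndex", data=wl + 1)
                ml.create_dataset("dataType", data=1)  # CW amplitude
                ml.create_dataset("dataTypeIndex", data=1)
                k += 1
        probe = nirs.create_group("probe")
        pr = montage_to_snirf_probe(m)
        probe.create_dataset("wavelengths", data=np.asarray(wavelengths, float))
        probe.create_dataset("sourcePos2D", data=pr["sourcePos2D"])
        probe.create_dataset("detectorPos2D", data=pr["detectorPos2D"])
    return path


def _h5str(ds) -> str:
    v = ds[()]
    return v.decode() if isinstance(v, bytes) else str(v)


def read_snirf(path: str | Path) -> RawIntensityRecording:
    """Read a continuous-wave SNIRF file written by :func:`write_snirf` (or any
    file using the same channel-major measurement-list layout)."""
    import h5py

    with h5py.File(path, "r") as f:
        data = f["/nirs/data1"]
        flat = np.asarray(data["dataTimeSeries"])
        time = np.asarray(data["time"])
        mls = sorted(
            (k for k in data.keys() if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        pairs = []
        wl_idx = []
        for k in mls:
            g = data[k]
            pairs.append((int(g["sourceIndex"][()]), int(g["detectorIndex"][()])))
            wl_idx.append(int(g["wavelengthIndex"][()]))
        n_wl = max(wl_idx)
        seen: list[tuple[int, int]] = []
        for p in pairs:
            if p not in seen:
                seen.append(p)
        n_ch = len(seen)
        arr = np.empty((flat.shape[0], n_ch, n_wl))
        for col, (p, w) in enumerate(zip(pairs, wl_idx)):
            arr[:, seen.index(p), w - 1] = flat[:, col]
        meta = f["/nirs/metaDataTags"]
        sid = _h5str(meta["SubjectID"])
        sex = _h5str(meta["sex"]) if "sex" in meta else "female"
        if len(time) > 1:
            fs = 1.0 / float(np.median(np.diff(time)))
        else:
            raise InputError(f"{path}: cannot infer sampling rate")
    return RawIntensityRecording(sid, sex, fs, arr)


# ---------------------------------------------------------------------------
# run configuration + end-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    output_dir: str = "nirsleep_out"
    cohort_dir: str | None = None          # read subjects from disk ...
    cohort_spec: CohortSpec | None = None  # ... or simulate them
    montage_path: str | None = None
    constants: OpticalConstants = field(default_factory=OpticalConstants)
    denoise: bool = True
    wavelet: str = "db4"
    wavelet_level: int = 5
    nuisance_bands: tuple[tuple[float, float], ...] = ((1.5, 2.5), (3.5, 4.5))
    cutoff_hz: float = 0.09
    legendre_max_order: int = 4
    include_global_mean: bool = True
    psd_method: str = "welch"
    analysis_band: tuple[float, float] = (0.0, 4.5)
    cardiac_band: tuple[float, float] = (1.0, 3.0)
    harmonic_band: tuple[float, float] = (3.0, 4.5)
    alpha: float = 0.05
    test_mode: str = "paired-over-frequency"
    hpod_band: tuple[float, float] = (0.01, 0.5)
    histogram_width_deg: int = 30
    min_duration_s: float = 0.0
    seed: int = 0
    figures: bool = True


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "cohort_spec" in raw and raw["cohort_spec"] is not None:
        spec = raw["cohort_spec"]
        if "effects" in spec:
            from .synthetic_data import GroupEffect

            spec["effects"] = tuple(
                GroupEffect(tuple(e["channels"]), e["chromophore"], e["sex"],
                            float(e["scale"]))
                for e in spec["effects"]
            )
        raw["cohort_spec"] = CohortSpec(**spec)
    if "constants" in raw and raw["constants"] is not None:
        c = raw["constants"]
        for k in ("wavelengths", "dpf"):
            if k in c:
                c[k] = tuple(c[k])
        if "extinction" in c:
            c["extinction"] = tuple(tuple(row) for row in c["extinction"])
        raw["constants"] = OpticalConstants(**c)
    for k in ("nuisance_bands",):
        if k in raw:
            raw[k] = tuple(tuple(b) for b in raw[k])
    for k in ("analysis_band", "cardiac_band", "harmonic_band", "hpod_band"):
        if k in raw:
            raw[k] = tuple(raw[k])
    return RunConfig(**raw)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _iter_pipeline_subjects(cfg: RunConfig, m: Montage):
    if cfg.cohort_spec is not None:
        for rec, _truth in iter_cohort(cfg.cohort_spec, cfg.constants, m):
            yield rec
    elif cfg.cohort_dir is not None:
        for rec in read_cohort(cfg.cohort_dir, min_duration_s=cfg.min_duration_s):
            yield rec
    else:
        raise InputError("config must provide cohort_dir or cohort_spec")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run generate/read -> preprocess -> analyze -> report; return the summary."""
    m = load_montage(cfg.montage_path) if cfg.montage_path else default_montage()
    idx = m.retained_index()
    ids = m.retained_ids
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    hemos: list[HemoSeries] = []      # spectral/phase path (no nuisance regression)
    clean: list[HemoSeries] = []      # FC path (nuisance-regressed)
    logger.info("stage 1/3: preprocessing")
    for rec in _iter_pipeline_subjects(cfg, m):
        h = preprocess_recording(rec, cfg.constants, denoise=cfg.denoise,
                                 wavelet=cfg.wavelet, level=cfg.wavelet_level)
        hemos.append(h)
        clean.append(
            nuisance_regress(h, cfg.cutoff_hz, cfg.legendre_max_order,
                             cfg.include_global_mean, bands=cfg.nuisance_bands,
                             channel_mask=idx)
        )
        logger.debug("preprocessed %s", h.subject_id)
    sexes = {h.sex for h in hemos}
    if len(sexes) < 2:
        raise GroupingError(
            f"group comparisons need both sexes; cohort has only {sorted(sexes)}"
        )

    summary: dict = {"n_subjects": len(hemos),
                     "n_female": sum(h.sex == "female" for h in hemos),
                     "n_male": sum(h.sex == "male" for h in hemos),
                     "montage": {"channels": m.n_channels, "retained": m.n_retained},
                     "alpha": cfg.alpha}

    logger.info("stage 2/3: group analyses")
    # -- activation maps: per-channel RMS amplitude of the preprocessed signals
    activation = {}
    for sex in ("female", "male"):
        sel = [h for h in clean if h.sex == sex]
        act = {ch: {} for ch in ("HbO", "HbR", "HbT")}
        for chrom in act:
            vals = np.mean(
                [np.sqrt(np.mean(h.chromophore(chrom)[:, idx] ** 2, axis=0))
                 for h in sel], axis=0)
            act[chrom] = vals
        activation[sex] = act
    summary["activation_rms"] = {
        s: {c: _jsonable(v) for c, v in a.items()} for s, a in activation.items()
    }

    # -- group PSD curves, peaks, shift
    psd: dict[str, dict[str, PSDResult]] = {}
    for chrom in ("HbO", "HbR"):
        psd[chrom] = {}
        for sex in ("female", "male"):
            psd[chrom][sex] = _group_psd(hemos, sex, chrom, idx, cfg)
    peaks = {}
    for chrom in ("HbO", "HbR"):
        both = _group_psd(hemos, None, chrom, idx, cfg)
        peaks[chrom] = {
            "cardiac_hz": peak_frequency(both, cfg.cardiac_band),
            "harmonic_hz": peak_frequency(both, cfg.harmonic_band),
        }
    shift = estimate_frequency_shift(
        psd["HbO"]["female"], psd["HbO"]["male"], cfg.cardiac_band
    )
    summary["psd"] = {
        "freqs": _jsonable(psd["HbO"]["female"].freqs),
        "power": {c: {s: _jsonable(p.power) for s, p in d.items()}
                  for c, d in psd.items()},
        "peaks": peaks,
        "male_shift_hz": shift,
    }

    # -- channel-wise tests
    tests = {}
    for chrom in ("HbO", "HbR"):
        res = channelwise_psd_test(
            hemos, chrom, alpha=cfg.alpha, mode=cfg.test_mode,
            band=cfg.analysis_band, channel_index=idx, channel_ids=ids,
        )
        tests[chrom] = {
            "results": [
                {"channel": r.channel, "t": r.t, "p": r.p} for r in res
            ],
            "significant_raw": significant_channels(res, cfg.alpha),
            "significant_fdr_bh": significant_channels(res, cfg.alpha, "fdr_bh"),
        }
    summary["channel_tests"] = {"mode": cfg.test_mode, **tests}

    # -- adjacency matrices
    fc = {}
    pairs = [("HbO", "HbO"), ("HbR", "HbR"), ("HbT", "HbT"), ("HbO", "HbR")]
    for pair in pairs:
        for sex in ("female", "male"):
            g = group_mean_fc(clean, sex, pair, channel_index=idx, channel_ids=ids)
            key = f"{pair[0]}x{pair[1]}_{sex}"
            entry = {"matrix": _jsonable(g.matrix)}
            if pair[0] == pair[1]:
                entry["strength"] = _jsonable(connectivity_strength(g))
                entry["homotopic"] = [
                    {"pair": list(p), "r": r} for p, r in homotopic_profile(g, m)
                ]
            else:
                entry["diagonal_mean"] = float(np.mean(np.diag(g.matrix)))
            fc[key] = entry
    summary["connectivity"] = fc

    # -- hPod
    hp = {}
    hp_res = {}
    for sex in ("female", "male"):
        r = hpod_cohort(hemos, sex, channel_index=idx, channel_ids=ids,
                        band=cfg.hpod_band)
        edges, counts = hpod_histogram(r, cfg.histogram_width_deg)
        hp_res[sex] = r
        hp[sex] = {
            "pooled_circular_mean_deg": r.pooled_circular_mean,
            "subject_means_deg": _jsonable(r.subject_means),
            "histogram_edges_deg": _jsonable(edges),
            "histogram_counts": _jsonable(counts),
        }
    t, p = hpod_group_test(hp_res["female"], hp_res["male"])
    hp["group_test"] = {"t": t, "p": p, "significant": bool(p < cfg.alpha)}
    summary["hpod"] = hp

    logger.info("stage 3/3: report")
    _write_tables(out_dir, summary, psd)
    if cfg.figures:
        _write_figures(out_dir, summary, psd, m, cfg)
    (out_dir / "summary.json").write_text(
        json.dumps(_jsonable(summary), sort_keys=True, indent=1)
    )
    return summary


def _group_psd(hemos, sex, chrom, idx, cfg: RunConfig) -> PSDResult:
    from .spectral import group_mean_psd

    return group_mean_psd(hemos, sex, chrom, method=cfg.psd_method,
                          mode="average-spectra", channel_index=idx)


def _write_tables(out_dir: Path, summary: dict, psd) -> None:
    rows = []
    for chrom, d in summary["channel_tests"].items():
        if chrom == "mode":
            continue
        sig = set(d["significant_raw"])
        sig_bh = set(d["significant_fdr_bh"])
        for r in d["results"]:
            rows.append({
                "channel": r["channel"], "chromophore": chrom,
                "t": r["t"], "p": r["p"],
                "significant_raw": r["channel"] in sig,
                "significant_fdr_bh": r["channel"] in sig_bh,
                "mode": summary["channel_tests"]["mode"],
                "alpha": summary["alpha"],
            })
    pd.DataFrame(rows).to_csv(out_dir / "channel_tests.tsv", sep="\t", index=False)
    rows = []
    for chrom, d in psd.items():
        for sex, p in d.items():
            for f, pw in zip(p.freqs, p.power):
                rows.append({"freq_hz": f, "power": pw, "group": sex,
                             "chromophore": chrom})
    pd.DataFrame(rows).to_csv(out_dir / "group_psd.tsv", sep="\t", index=False)


def _write_figures(out_dir: Path, summary: dict, psd, m: Montage, cfg: RunConfig) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    idx = m.retained_index()
    chans = [m.channels[i] for i in idx]

    # activation maps
    fig, axes = plt.subplots(2, 3, figsize=(10, 6))
    for i, sex in enumerate(("female", "male")):
        for j, chrom in enumerate(("HbO", "HbR", "HbT")):
            vals = summary["activation_rms"][sex][chrom]
            grid = topographic_map(vals, m, resolution=64)
            ax = axes[i][j]
            ax.imshow(grid, origin="lower", extent=(0, 1, 0, 1), cmap="RdBu_r")
            ax.scatter([c.position[0] for c in chans],
                       [c.position[1] for c in chans], s=4, c="k")
            ax.set_title(f"{sex} {chrom} (RMS)")
            ax.set_xticks([]); ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(out_dir / "fig_activation_maps.png", dpi=110)
    plt.close(fig)

    # group PSD, raw + log-smoothed
    fig, axes = plt.subplots(2, 2, figsize=(10, 6), sharex=True)
    for j, chrom in enumerate(("HbO", "HbR")):
        for sex, color in (("female", "tab:red"), ("male", "tab:blue")):
            p = psd[chrom][sex]
            sel = p.band(0, 4.5)
            axes[0][j].plot(p.freqs[sel], p.power[sel], color=color, label=sex)
            sm = smooth_log_psd(p, 9)
            axes[1][j].plot(sm.freqs[sel], sm.power[sel], color=color, label=sex)
        axes[0][j].set_title(f"{chrom} group PSD")
        axes[1][j].set_xlabel("frequency (Hz)")
        axes[1][j].set_ylabel("log10 power (smoothed)")
        axes[0][j].legend()
    fig.tight_layout()
    fig.savefig(out_dir / "fig_group_psd.png", dpi=110)
    plt.close(fig)

    # HbO curves with the male curve displaced by the estimated shift
    shift = summary["psd"]["male_shift_hz"]
    fig, ax = plt.subplots(figsize=(6, 4))
    pf, pm = psd["HbO"]["female"], psd["HbO"]["male"]
    smf, smm = smooth_log_psd(pf, 9), smooth_log_psd(pm, 9)
    sel = pf.band(0, 4.5)
    ax.plot(pf.freqs[sel], smf.power[sel], "tab:red", label="female")
    ax.plot(pm.freqs[sel] - shift, smm.power[sel], "tab:blue",
            label=f"male (shifted {-shift:+.3f} Hz)")
    ax.set_xlabel("frequency (Hz)"); ax.set_ylabel("log10 power")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "fig_psd_shifted.png", dpi=110)
    plt.close(fig)

    # channel-test link figure
    fig, axes = plt.subplots(1, 2, figsize=(10, 5))
    for ax, chrom in zip(axes, ("HbO", "HbR")):
        d = summary["channel_tests"][chrom]
        sig = set(d["significant_raw"])
        pmap = {r["channel"]: (r["t"], r["p"]) for r in d["results"]}
        for c in chans:
            col = "tab:red" if c.id in sig else "lightgray"
            ax.scatter(*c.position, s=60, c=col, zorder=3)
            if c.id in sig:
                t, p = pmap[c.id]
                ax.annotate(f"ch{c.id}\nt={t:.2f}\np={p:.3g}", c.position,
                            fontsize=6, textcoords="offset points", xytext=(5, 5))
        ax.set_title(f"{chrom}: significant channels (p < {summary['alpha']})")
        ax.set_xticks([]); ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(out_dir / "fig_channel_tests.svg")
    plt.close(fig)

    # adjacency matrices
    fig, axes = plt.subplots(2, 4, figsize=(14, 7))
    pairs = ["HbOxHbO", "HbRxHbR", "HbTxHbT", "HbOxHbR"]
    for j, pairname in enumerate(pairs):
        for i, sex in enumerate(("female", "male")):
            mat = np.array(summary["connectivity"][f"{pairname}_{sex}"]["matrix"])
            ax = axes[i][j]
            im = ax.imshow(mat, vmin=-1, vmax=1, cmap="RdBu_r")
            ax.set_title(f"{pairname} {sex}", fontsize=9)
    fig.colorbar(im, ax=axes, shrink=0.6)
    fig.savefig(out_dir / "fig_adjacency.png", dpi=110)
    plt.close(fig)

    # hPod histograms (standard and polar)
    fig = plt.figure(figsize=(10, 5))
    for i, sex in enumerate(("female", "male")):
        edges = np.array(summary["hpod"][sex]["histogram_edges_deg"])
        counts = np.array(summary["hpod"][sex]["histogram_counts"])
        ax = fig.add_subplot(2, 2, i + 1)
        ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge",
               color="tab:purple", edgecolor="k")
        ax.set_title(f"{sex} hPod (deg)")
        axp = fig.add_subplot(2, 2, i + 3, projection="polar")
        axp.bar(np.deg2rad(edges[:-1]), counts, width=np.deg2rad(np.diff(edges)),
                align="edge", color="tab:purple", edgecolor="k")
    fig.tight_layout()
    fig.savefig(out_dir / "fig_hpod_hist.png", dpi=110)
    plt.close(fig)

    # hPod group test
    fig, ax = plt.subplots(figsize=(4, 4))
    means = [summary["hpod"][s]["pooled_circular_mean_deg"] for s in ("female", "male")]
    ax.bar(["female", "male"], means, color=["tab:red", "tab:blue"])
    gt = summary["hpod"]["group_test"]
    ax.set_ylabel("pooled circular mean hPod (deg)")
    ax.set_title(f"t = {gt['t']:.2f}, p = {gt['p']:.3g}")
    fig.tight_layout()
    fig.savefig(out_dir / "fig_hpod_test.png", dpi=110)
    plt.close(fig)
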