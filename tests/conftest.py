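import numpy as np
import pytest

from nirsleep.montage import default_montage
from nirsleep.phase import hpod
from nirsleep.preprocess import preprocess_recording
from nirsleep.spectral import PSDResult, compute_psd
from nirsleep.synthetic_data import CohortSpec, iter_cohort


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small mixed-sex cohort (4 F / 4 M, 2 min) preprocessed to HemoSeries."""
    spec = CohortSpec(n_female=4, n_male=4, duration_s=120.0, seed=42)
    hemos = [preprocess_recording(rec) for rec, _ in iter_cohort(spec)]
    return spec, hemos


@pytest.fixture(scope="session")
def default_cohort_stats(montage):
    """One streaming pass over the default cohort (51 F / 48 M, 9 min, seed 0).

    Accumulates the pooled average-spectra group HbO PSD of the channel-mean
    series and every subject's per-channel hPod angles.
    """
    spec = CohortSpec()  # all defaults, seed 0
    idx = montage.retained_index()
    psd_sum = None
    freqs = None
    n = 0
    angles = []
    for rec, _truth in iter_cohort(spec):
        h = preprocess_recording(rec)
        res = compute_psd(h.hbo[:, idx].mean(axis=1), h.fs, method="welch")
        psd_sum = res.power if psd_sum is None else psd_sum + res.power
        freqs = res.freqs
        n += 1
        angles.append(hpod(h.hbo[:, idx], h.hbr[:, idx], fs=h.fs))
    pooled_psd = PSDResult(freqs, psd_sum / n, spec.fs, "welch")
    return {"spec": spec, "psd_hbo_pooled": pooled_psd,
            "hpod_angles": np.vstack(angles)}
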