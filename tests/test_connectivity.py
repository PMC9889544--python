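import numpy as np
import pytest

from nirsleep.connectivity import (
    FCMatrix,
    connectivity_strength,
    fc_matrix,
    group_mean_fc,
    homotopic_profile,
)
from nirsleep.exceptions import ChromophoreError, GroupingError, PairingError
from nirsleep.preprocess import HemoSeries, preprocess_recording
from nirsleep.synthetic_data import CohortSpec, iter_cohort

FS = 15.625


def _hemo(hbo, hbr=None, sex="female", sid="s"):
    if hbr is None:
        hbr = -0.3 * hbo
    return HemoSeries(sid, sex, FS, hbo, hbr)


class TestFcMatrix:
    def test_exact_copies_correlate_to_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        h = _hemo(np.column_stack([x, x]))
        r = fc_matrix(h, ("HbO", "HbO")).matrix
        assert np.isclose(r[0, 1], 1.0)

    def test_negated_channel_anticorrelates(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        h = _hemo(np.column_stack([x, -x]))
        assert np.isclose(fc_matrix(h).matrix[0, 1], -1.0)

    def test_toy_table_matches_hand_pearson(self):
        hbo = np.array(
            [[1.0, 2.0, 0.5], [2.0, 1.0, 1.5], [3.0, 4.0, 2.0],
             [4.0, 3.0, 0.0], [5.0, 5.0, 3.0]]
        )
        r = fc_matrix(_hemo(hbo)).matrix
        for m in range(3):
            for n in range(3):
                a, b = hbo[:, m], hbo[:, n]
                am, bm = a - a.mean(), b - b.mean()
                ref = (am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum())
                assert np.isclose(r[m, n], ref, atol=1e-12)

    def test_same_chromophore_invariants(self):
        rng = np.random.default_rng(2)
        h = _hemo(rng.normal(size=(80, 5)))
        fc = fc_matrix(h)
        assert np.allclose(fc.matrix, fc.matrix.T)
        assert np.allclose(np.diag(fc.matrix), 1.0)
        assert np.all(np.abs(fc.matrix) <= 1.0)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(60, 4))
        scale = np.array([2.0, 0.5, 10.0, 1.0])
        shift = np.array([1.0, -5.0, 0.0, 3.0])
        r1 = fc_matrix(_hemo(x)).matrix
        r2 = fc_matrix(_hemo(x * scale + shift)).matrix
        assert np.allclose(r1, r2, atol=1e-10)

    def test_zero_variance_channel_flagged_not_nan(self):
        rng = np.random.default_rng(4)
        hbo = rng.normal(size=(50, 3))
        hbo[:, 1] = 7.0
        fc = fc_matrix(_hemo(hbo))
        assert not fc.valid[1]
        assert np.all(np.isfinite(fc.matrix))
        assert np.allclose(fc.matrix[1, :], 0.0)

    def test_cross_chromophore_diagonal_negative_for_antiphase(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(200, 4))
        fc = fc_matrix(_hemo(x, -0.3 * x), ("HbO", "HbR"))
        assert np.all(np.diag(fc.matrix) < -0.99)


class TestGroupMeanFc:
    def test_single_subject_group_is_identity_operation(self):
        rng = np.random.default_rng(6)
        h = _hemo(rng.normal(size=(64, 4)))
        g = group_mean_fc([h], "female")
        assert np.allclose(g.matrix, fc_matrix(h).matrix, atol=1e-12)

    def test_opposite_correlations_pool_to_zero(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=100)
        n1, n2 = rng.normal(size=100), rng.normal(size=100)
        # construct two subjects with r and -r between their two channels
        a = np.column_stack([base, base + n1])
        b = np.column_stack([base, -(base + n1)])
        g = group_mean_fc([_hemo(a, sid="a"), _hemo(b, sid="b")], "female")
        assert abs(g.matrix[0, 1]) < 1e-10

    def test_matches_fisher_loop_oracle(self):
        rng = np.random.default_rng(8)
        cohort = [_hemo(rng.normal(size=(50, 3)), sid=f"s{i}") for i in range(5)]
        g = group_mean_fc(cohort, "female")
        mats = [fc_matrix(h).matrix for h in cohort]
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                zs = [np.arctanh(np.clip(m[i, j], -1 + 1e-12, 1 - 1e-12)) for m in mats]
                assert np.isclose(g.matrix[i, j], np.tanh(np.mean(zs)), atol=1e-10)

    def test_empty_group_raises(self):
        with pytest.raises(GroupingError):
            group_mean_fc([_hemo(np.random.normal(size=(30, 2)))], "male")


class TestStrengthAndHomotopy:
    def test_all_ones_strength_one(self):
        fc = FCMatrix(np.ones((4, 4)), ("HbO", "HbO"), (1, 2, 3, 4), np.ones(4, bool))
        assert np.allclose(connectivity_strength(fc), 1.0)

    def test_identity_strength_zero(self):
        fc = FCMatrix(np.eye(3), ("HbO", "HbO"), (1, 2, 3), np.ones(3, bool))
        assert np.allclose(connectivity_strength(fc), 0.0)

    def test_toy_row_means(self):
        m = np.array([[1.0, 0.2, 0.4], [0.2, 1.0, 0.6], [0.4, 0.6, 1.0]])
        fc = FCMatrix(m, ("HbO", "HbO"), (1, 2, 3), np.ones(3, bool))
        assert np.allclose(connectivity_strength(fc), [0.3, 0.4, 0.5])

    def test_cross_matrix_rejected(self):
        fc = FCMatrix(np.eye(3), ("HbO", "HbR"), (1, 2, 3), np.ones(3, bool))
        with pytest.raises(ChromophoreError):
            connectivity_strength(fc)

    def test_identity_matrix_homotopic_entries_zero(self, montage):
        ids = tuple(c.id for c in montage.channels)
        fc = FCMatrix(np.eye(52), ("HbO", "HbO"), ids, np.ones(52, bool))
        prof = homotopic_profile(fc, montage)
        assert len(prof) == 26
        assert all(r == 0.0 for _, r in prof)

    def test_missing_pairs_raise(self, montage):
        fc = FCMatrix(np.eye(2), ("HbO", "HbO"), (100, 101), np.ones(2, bool))
        with pytest.raises(PairingError):
            homotopic_profile(fc, montage)


class TestSyntheticCohortStructure:
    """Correlation structure the generator injects, verified via the pipeline."""

    def test_homotopic_pairs_exceed_global_mean(self, montage):
        spec = CohortSpec(n_female=4, n_male=0, duration_s=120, seed=17)
        idx = montage.retained_index()
        ids = montage.retained_ids
        hemos = [preprocess_recording(r) for r, _ in iter_cohort(spec)]
        g = group_mean_fc(hemos, "female", channel_index=idx, channel_ids=ids)
        prof = homotopic_profile(g, montage)
        hom = np.mean([r for _, r in prof])
        off = g.matrix[~np.eye(len(ids), dtype=bool)].mean()
        assert hom > off

    def test_uncorrelated_noise_cohort_shows_no_homotopic_excess(self, montage):
        rng = np.random.default_rng(19)
        ids = montage.retained_ids
        idx = montage.retained_index()
        cohort = [_hemo(rng.normal(size=(400, 52)), sid=f"s{i}") for i in range(4)]
        g = group_mean_fc(cohort, "female", channel_index=idx, channel_ids=ids)
        prof = homotopic_profile(g, montage)
        hom = np.mean([r for _, r in prof])
        off = g.matrix[~np.eye(len(ids), dtype=bool)].mean()
        assert abs(hom - off) < 0.05

    def test_hbo_hbr_diagonal_negative_on_synthetic_subject(self, tiny_cohort, montage):
        _, hemos = tiny_cohort
        idx = montage.retained_index()
        fc = fc_matrix(hemos[0], ("HbO", "HbR"), channel_index=idx)
        assert np.mean(np.diag(fc.matrix)) < 0
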