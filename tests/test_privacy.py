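import numpy as np
import pytest
from scipy import stats as spstats

from heartedge import (
    FeatureMatrix,
    PrivacyConfig,
    dbscan,
    epsilon_policy,
    laplace_noise,
    obfuscate,
    privacy_gate,
    sensitivity,
)
from heartedge.errors import BadInputError, DegenerateDataError


def _matrix(values, ids=None, labels=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"r{i}" for i in range(values.shape[0])]
    return FeatureMatrix(record_ids=ids, values=values, labels=labels)


class TestEpsilonPolicy:
    def test_three_sigma_rule(self):
        col = np.random.default_rng(0).normal(scale=1.0, size=10**5)
        assert epsilon_policy(col) == pytest.approx(3 * np.std(col))

    def test_two_point_column(self):
        assert epsilon_policy([0.0, 2.0]) == pytest.approx(3.0)  # population sigma = 1

    def test_constant_column_degenerate(self):
        with pytest.raises(DegenerateDataError):
            epsilon_policy([5.0, 5.0, 5.0])


class TestSensitivity:
    def test_range(self):
        assert sensitivity([1.0, 5.0]) == 4.0
        assert sensitivity([3.0, 3.0]) == 0.0

    def test_equals_max_pairwise_difference(self):
        col = np.random.default_rng(1).uniform(0, 1, 100)
        brute = max(abs(a - b) for a in col for b in col)
        assert sensitivity(col) == pytest.approx(brute)


class TestLaplaceNoise:
    def test_symmetry_and_std(self):
        z = laplace_noise(b=1.0, n=10**6, seed=0)
        assert abs(z.mean()) < 0.01
        assert z.std() == pytest.approx(np.sqrt(2.0), rel=0.01)

    def test_density_ratio_bound(self):
        # Laplace(b) with b = Delta/eps satisfies p(t)/p(t+Delta) <= e^eps
        delta, eps = 3.7, 2.1
        b = delta / eps
        t = np.linspace(-20, 20, 2001)
        ratio = spstats.laplace.pdf(t, scale=b) / spstats.laplace.pdf(t + delta, scale=b)
        assert np.max(ratio) <= np.exp(eps) * (1 + 1e-12)

    def test_goodness_of_fit(self):
        b = 0.8
        z = laplace_noise(b=b, n=10**5, seed=7)
        res = spstats.kstest(z, spstats.laplace(scale=b).cdf)
        assert res.pvalue > 0.01

    def test_invalid_scale(self):
        with pytest.raises(BadInputError):
            laplace_noise(b=0.0, n=5, seed=0)


class TestDBSCAN:
    def test_tight_ball_is_one_cluster(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(scale=0.1, size=(10, 3))
        labels, noise = dbscan(pts, eps_distance=1.0, minpts=4)
        assert not noise.any()
        assert np.unique(labels).size == 1

    def test_far_point_is_noise(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(scale=0.1, size=(10, 3)), [[100.0, 100.0, 100.0]]])
        labels, noise = dbscan(pts, eps_distance=1.0, minpts=4)
        assert noise[-1]
        assert not noise[:-1].any()

    def test_invalid_inputs(self):
        with pytest.raises(BadInputError):
            dbscan(np.zeros((3, 2)), eps_distance=0.0, minpts=4)
        with pytest.raises(BadInputError):
            dbscan(np.array([[np.nan, 0.0]]), eps_distance=1.0, minpts=4)


class TestObfuscate:
    def _reference(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        vals = np.column_stack([
            rng.normal(10, 2, n), rng.uniform(0, 1, n), rng.exponential(1.0, n),
        ])
        return _matrix(vals)

    def test_scale_identity_b_equals_delta_over_eps(self):
        ref = self._reference()
        released = _matrix(ref.values[:20], ids=[f"t{i}" for i in range(20)])
        res = obfuscate(released, PrivacyConfig(seed=0), ref)
        for j in range(3):
            col = ref.values[:, j]
            eps = 3 * np.std(col)
            delta = col.max() - col.min()
            assert res.epsilon[j] == eps
            assert res.sensitivity[j] == delta
            assert res.noise_scale_b[j] == delta / eps  # exact, machine precision

    def test_shape_ids_and_reproducibility(self):
        ref = self._reference()
        released = _matrix(ref.values[:30])
        a = obfuscate(released, PrivacyConfig(seed=5), ref)
        b = obfuscate(released, PrivacyConfig(seed=5), ref)
        assert np.array_equal(a.obfuscated.values, b.obfuscated.values)
        assert a.obfuscated.values.shape == released.values.shape
        assert a.obfuscated.record_ids == released.record_ids
        assert a.obfuscated.feature_names == released.feature_names
        c = obfuscate(released, PrivacyConfig(seed=6), ref)
        assert not np.array_equal(a.obfuscated.values, c.obfuscated.values)

    def test_noise_is_record_keyed_not_order_keyed(self):
        ref = self._reference()
        released = _matrix(ref.values[:10])
        shuffled = released.subset([3, 1, 0, 2, 5, 4, 9, 7, 8, 6])
        a = obfuscate(released, PrivacyConfig(seed=2), ref)
        b = obfuscate(shuffled, PrivacyConfig(seed=2), ref)
        for i, rid in enumerate(shuffled.record_ids):
            j = released.record_ids.index(rid)
            assert np.array_equal(b.obfuscated.values[i], a.obfuscated.values[j])

    def test_mean_absolute_perturbation_matches_laplace(self):
        # E|Laplace(b)| = b
        ref = self._reference()
        released = _matrix(np.tile(ref.values.mean(axis=0), (10**4, 1)))
        res = obfuscate(released, PrivacyConfig(seed=1), ref)
        pert = np.abs(res.obfuscated.values - released.values)
        assert np.allclose(pert.mean(axis=0), res.noise_scale_b, rtol=0.03)

    def test_tiered_scales_outlier_noise_by_kappa(self):
        rng = np.random.default_rng(3)
        vals = np.vstack([rng.normal(size=(40, 3)) * 0.3, [[50.0, 50.0, 50.0]]])
        released = _matrix(vals)
        ref = self._reference()
        flat = obfuscate(released, PrivacyConfig(seed=4, tiered=False), ref)
        tier = obfuscate(released, PrivacyConfig(seed=4, tiered=True, tier_factor=2.0), ref)
        assert flat.outlier_mask[-1] and not flat.outlier_mask[:-1].any()
        noise_flat = flat.obfuscated.values - vals
        noise_tier = tier.obfuscated.values - vals
        assert np.allclose(noise_tier[-1], 2.0 * noise_flat[-1])
        assert np.allclose(noise_tier[:-1], noise_flat[:-1])

    def test_degenerate_reference_column(self):
        ref = _matrix(np.column_stack([np.ones(50), np.arange(50), np.arange(50)]))
        with pytest.raises(DegenerateDataError):
            obfuscate(_matrix(ref.values[:5]), PrivacyConfig(), ref)


class TestPrivacyGate:
    def _setup(self):
        rng = np.random.default_rng(0)
        ref = _matrix(rng.normal(size=(100, 3)))
        ftest = _matrix(rng.normal(size=(10, 3)), ids=[f"t{i}" for i in range(10)])
        inference = rng.choice([-1, 1], size=10)
        return ref, ftest, inference

    def test_non_critical_with_privacy_on_gets_obfuscated_no_inference(self):
        ref, ftest, inference = self._setup()
        payload = privacy_gate(ftest, inference, P=1, stakeholder="non_critical",
                               config=PrivacyConfig(seed=0), reference=ref)
        assert payload.privacy_applied
        assert payload.inference is None
        assert not np.array_equal(payload.features.values, ftest.values)
        assert "inference" not in payload.to_dict()

    def test_critical_always_gets_raw_and_inference(self):
        ref, ftest, inference = self._setup()
        payload = privacy_gate(ftest, inference, P=1, stakeholder="critical",
                               config=PrivacyConfig(seed=0), reference=ref)
        assert not payload.privacy_applied
        assert np.array_equal(payload.features.values, ftest.values)
        assert np.array_equal(payload.inference, inference)

    def test_privacy_off_shares_everything(self):
        ref, ftest, inference = self._setup()
        payload = privacy_gate(ftest, inference, P=0, stakeholder="non_critical",
                               config=PrivacyConfig(seed=0), reference=ref)
        assert not payload.privacy_applied
        assert np.array_equal(payload.features.values, ftest.values)
        assert np.array_equal(payload.inference, inference)

    def test_unknown_stakeholder_rejected(self):
        ref, ftest, inference = self._setup()
        with pytest.raises(BadInputError):
            privacy_gate(ftest, inference, P=1, stakeholder="press",
                         config=PrivacyConfig(), reference=ref)
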