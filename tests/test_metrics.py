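"""Metric suite: oracle agreement, stub-model arithmetic, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shapearena.metrics import (
    MetricReport,
    compactness,
    generalization_ability,
    ks_statistic,
    latent_ambiguity_score,
    likeness_dsi,
    normality_fraction,
    specificity,
)


def brute_force_ks(a, b):
    """Sup of |ECDF_a - ECDF_b| over every breakpoint."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    points = np.concatenate([a, b])
    best = 0.0
    for x in points:
        best = max(best, abs((a <= x).mean() - (b <= x).mean()))
    return best


class StubModel:
    """Dictionary-driven generative contract for metric arithmetic tests."""

    def __init__(self, recon=None, samples=None, codes=None, recodes=None):
        self._recon = recon or {}
        self._samples = samples or []
        self._codes = codes or {}
        self._recodes = recodes or {}

    def reconstruct(self, x):
        return self._recon[x]

    def sample(self, n, random_state=None):
        return self._samples[:n]

    def encode(self, x):
        return np.asarray(self._codes[x], float)

    def decode(self, z):
        return ("decoded", tuple(np.round(np.asarray(z), 9)))

    def reencode(self, z):
        return np.asarray(self._recodes[tuple(np.round(np.asarray(z), 9))], float)


class TestKS:
    def test_identical_and_disjoint(self):
        assert ks_statistic([1, 2, 3], [1, 2, 3]) == 0.0
        assert ks_statistic([1, 2], [5, 6]) == 1.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=20),
        b=st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=20),
    )
    def test_matches_bruteforce_ecdf_sup(self, a, b):
        assert ks_statistic(a, b) == pytest.approx(brute_force_ks(a, b), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ks_statistic([], [1.0])


class TestGeneralizationAbility:
    def test_identity_model_zero(self):
        model = StubModel(recon={"a": "a", "b": "b"})
        dist = lambda x, y: 0.0 if x == y else 1.0
        assert generalization_ability(model, ["a", "b"], dist) == 0.0

    def test_arithmetic_mean_of_distances(self):
        model = StubModel(recon={"a": "ra", "b": "rb", "c": "rc"})
        table = {("a", "ra"): 1.0, ("b", "rb"): 2.0, ("c", "rc"): 3.0}
        dist = lambda x, y: table[(x, y)]
        assert generalization_ability(model, ["a", "b", "c"], dist) == 2.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            generalization_ability(StubModel(), [], lambda x, y: 0.0)


class TestSpecificity:
    def test_replaying_generator_is_exactly_zero(self):
        model = StubModel(samples=["a", "b"])
        dist = lambda x, y: 0.0 if x == y else 7.0
        assert specificity(model, ["a", "b"], 2, dist) == 0.0

    def test_min_over_real_set(self):
        model = StubModel(samples=["s"])
        table = {("r1", "s"): 3.0, ("r2", "s"): 1.0, ("r3", "s"): 2.0}
        dist = lambda x, y: table[(x, y)]
        assert specificity(model, ["r1", "r2", "r3"], 1, dist) == 1.0

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(0)
        reals = [f"r{i}" for i in range(5)]
        samples = [f"s{j}" for j in range(4)]
        table = {(r, s): rng.random() for r in reals for s in samples}
        dist = lambda x, y: table[(x, y)]
        model = StubModel(samples=samples)
        expected = np.mean([min(table[(r, s)] for r in reals) for s in samples])
        assert specificity(model, reals, 4, dist) == pytest.approx(expected)

    def test_far_outlier_never_decreases_specificity(self):
        rng = np.random.default_rng(1)
        reals = list(range(4))
        base = [10.0, 11.0, 12.0]
        dist = lambda r, s: abs(r - s)
        m1 = StubModel(samples=base)
        m2 = StubModel(samples=base + [1e6])
        s1 = specificity(m1, reals, 3, dist)
        s2 = specificity(m2, reals, 4, dist)
        assert s2 >= s1


class TestLikeness:
    def test_hand_computed_three_plus_three(self):
        """3 real + 3 synthetic points on a line; every pair enumerated."""
        real = [0.0, 1.0, 2.0]
        synth = [10.0, 11.0, 12.0]
        dist = lambda x, y: abs(x - y)
        icd = [1.0, 2.0, 1.0]  # both sets have identical intra distances
        bcd = [abs(r - s) for r in real for s in synth]  # 8..12
        expected = 0.5 * (brute_force_ks(icd, bcd) + brute_force_ks(icd, bcd))
        got = likeness_dsi(real, synth, dist)
        assert got == pytest.approx(expected)
        assert got == 1.0  # intra (<=2) and cross (>=8) supports are disjoint

    def test_far_sets_score_at_least_identical_sets(self):
        rng = np.random.default_rng(2)
        real = list(rng.normal(0, 1, 15))
        near = list(rng.normal(0, 1, 15))
        far = list(rng.normal(50, 1, 15))
        dist = lambda x, y: abs(x - y)
        near_score = likeness_dsi(real, near, dist)
        far_score = likeness_dsi(real, far, dist)
        assert 0.0 <= near_score <= 1.0
        assert 0.0 <= far_score <= 1.0
        assert near_score <= far_score

    def test_degenerate_identical_set_still_computed(self):
        real = [1.0, 1.0, 1.0]
        synth = [1.0, 1.0]
        value = likeness_dsi(real, synth, lambda x, y: abs(x - y))
        assert 0.0 <= value <= 1.0

    def test_minimum_sizes(self):
        with pytest.raises(ValueError):
            likeness_dsi([1.0], [1.0, 2.0], lambda x, y: abs(x - y))


class TestNormality:
    def test_normal_latents_near_alpha(self):
        rng = np.random.default_rng(3)
        Z = rng.standard_normal((500, 40))
        frac = normality_fraction(Z, alpha=0.05)
        assert 0.0 <= frac <= 15.0

    def test_two_point_mass_always_rejected(self):
        rng = np.random.default_rng(4)
        Z = rng.choice([0.0, 10.0], size=(500, 5))
        assert normality_fraction(Z) == 100.0

    def test_lognormal_rejected(self):
        rng = np.random.default_rng(5)
        Z = rng.lognormal(size=(500, 1))
        assert normality_fraction(Z) == 100.0

    def test_constant_dimension_warned_and_rejected(self):
        Z = np.concatenate(
            [np.ones((50, 1)), np.random.default_rng(6).normal(size=(50, 1))],
            axis=1,
        )
        with pytest.warns(UserWarning, match="constant"):
            frac = normality_fraction(Z)
        assert frac >= 50.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            normality_fraction(np.zeros((5, 2)))


class TestLatentAmbiguity:
    def test_fixed_point_reencoding_gives_zero(self):
        codes = {"a": [1.0, 0.0], "b": [0.0, 1.0], "c": [1.0, 1.0]}
        model = StubModel(
            codes=codes,
            recodes={tuple(v): v for v in codes.values()},
        )
        assert latent_ambiguity_score(model, ["a", "b", "c"]) == 0.0

    def test_hand_computed_ratio(self):
        codes = {"a": [0.0], "b": [2.0], "c": [4.0]}
        recodes = {(0.0,): [1.0], (2.0,): [2.0], (4.0,): [3.0]}
        model = StubModel(codes=codes, recodes=recodes)
        drift = np.mean([1.0, 0.0, 1.0])
        base = np.mean([2.0, 4.0, 2.0, 2.0, 4.0, 2.0])
        assert latent_ambiguity_score(model, ["a", "b", "c"]) == pytest.approx(
            drift / base
        )

    def test_identical_encodings_undefined(self):
        codes = {"a": [1.0], "b": [1.0]}
        model = StubModel(codes=codes, recodes={(1.0,): [1.0]})
        with pytest.raises(ValueError, match="undefined"):
            latent_ambiguity_score(model, ["a", "b"])


class TestCompactness:
    def test_pca_reports_mode_count(self, population_2d):
        from shapearena.statistical import fit_ssm

        model = fit_ssm(population_2d.landmark_matrix("train"))
        assert compactness(model) == model.n_components_ == 3

    def test_network_reports_configured_latent(self):
        from shapearena.neural import Autoencoder

        assert compactness(Autoencoder(latent_dim=512)) == 512

    def test_split_latent_reported_as_pair(self):
        from shapearena.neural import AppearanceDeformableAutoencoder

        model = AppearanceDeformableAutoencoder(
            latent_dim=1024, appearance_latent_dim=64
        )
        assert compactness(model) == (1024, 64)
        row = MetricReport("adae", 10, 0, compactness=compactness(model))
        assert row.to_dict()["compactness"] == "1024+64"
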