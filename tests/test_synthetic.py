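"""Synthetic population generator: templates, modes, instances, populations."""

import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator

from shapearena import synthetic as syn
from shapearena.representation import landmarks_to_label
from shapearena.synthetic import InstanceRejected


class TestTemplate:
    def test_thorax_has_five_structures_two_small(self, template_2d):
        labels = template_2d.structures
        assert len(labels) == 5
        areas = {s: (template_2d.label_image == s).sum() for s in labels}
        largest = max(areas.values())
        small = [s for s in labels if areas[s] < 0.05 * largest]
        assert len(small) >= 2
        assert all(areas[s] > 0 for s in labels)

    def test_deterministic_for_fixed_seed(self, template_2d):
        again = syn.build_template("thorax-like", (64, 64), seed=0)
        assert np.array_equal(again.label_image, template_2d.label_image)
        assert np.array_equal(again.landmarks, template_2d.landmarks)
        assert np.array_equal(again.appearance_image, template_2d.appearance_image)

    def test_label_is_rasterized_landmarks(self, template_2d):
        raster = landmarks_to_label(
            template_2d.landmarks, template_2d.grid_shape, template_2d.layout
        )
        assert np.array_equal(raster, template_2d.label_image)

    def test_3d_template_roundtrip_and_appearance(self, template_3d):
        assert template_3d.label_image.ndim == 3
        assert len(template_3d.structures) >= 3
        raster = landmarks_to_label(
            template_3d.landmarks, template_3d.grid_shape, template_3d.layout
        )
        assert np.array_equal(raster, template_3d.label_image)
        assert template_3d.appearance_image.min() >= 0
        assert template_3d.appearance_image.max() <= 1

    def test_unknown_kind_and_small_grid_rejected(self):
        with pytest.raises(ValueError, match="unknown template kind"):
            syn.build_template("femur-like", (64, 64))
        with pytest.raises(ValueError, match="at least 16"):
            syn.build_template("thorax-like", (8, 64))


class TestDeformationBasis:
    def test_single_mode(self, template_2d):
        basis = syn.build_deformation_basis(template_2d, k=1, seed=3)
        assert basis.modes.shape[0] == 1

    def test_modes_linearly_independent(self, basis_2d):
        flat = basis_2d.modes.reshape(basis_2d.k, -1)
        gram = flat @ flat.T
        assert np.linalg.matrix_rank(gram) == 3

    def test_modes_zero_mean(self, basis_2d):
        for mode in basis_2d.modes:
            assert np.abs(mode.mean(axis=(1, 2))).max() < 1e-9

    def test_deterministic(self, template_2d, basis_2d):
        again = syn.build_deformation_basis(template_2d, k=3, seed=1)
        assert np.array_equal(again.modes, basis_2d.modes)

    def test_validation(self, template_2d):
        with pytest.raises(ValueError, match="degrees of freedom"):
            syn.build_deformation_basis(template_2d, k=10**7)
        with pytest.raises(ValueError, match="k must be"):
            syn.build_deformation_basis(template_2d, k=0)
        with pytest.raises(ValueError, match="amplitudes"):
            syn.build_deformation_basis(template_2d, k=2, amplitudes=[1.0, -1.0])


class TestInstance:
    def test_zero_coefficients_reproduce_template(self, template_2d, basis_2d):
        inst = syn.sample_instance(template_2d, basis_2d, [0, 0, 0], 0.0, seed=0)
        assert np.array_equal(inst.landmarks, template_2d.landmarks)
        assert np.array_equal(inst.label, template_2d.label_image)
        assert np.allclose(inst.appearance, template_2d.appearance_image)

    def test_displacement_linear_in_coefficients(self, template_2d, basis_2d):
        c = np.array([1.5, -0.7, 0.4])
        plus = syn.sample_instance(template_2d, basis_2d, c, 0.0, seed=0)
        minus = syn.sample_instance(template_2d, basis_2d, -c, 0.0, seed=0)
        d_plus = plus.landmarks - template_2d.landmarks
        d_minus = minus.landmarks - template_2d.landmarks
        assert np.allclose(d_plus, -d_minus, atol=1e-12)

    def test_single_mode_displacement_matches_field(self, template_2d, basis_2d):
        """Landmark displacement equals the mode field interpolated at the
        landmark positions, checked with an independent interpolator."""
        amp = basis_2d.amplitudes[0]
        inst = syn.sample_instance(template_2d, basis_2d, [amp, 0, 0], 0.0, seed=0)
        pts = template_2d.landmarks.reshape(-1, 2)
        axes = [np.arange(s) for s in template_2d.grid_shape]
        expected = np.stack(
            [
                RegularGridInterpolator(axes, amp * basis_2d.modes[0, c])(pts)
                for c in range(2)
            ],
            axis=1,
        )
        got = (inst.landmarks - template_2d.landmarks).reshape(-1, 2)
        assert np.allclose(got, expected, atol=1e-8)

    def test_out_of_grid_rejected(self, template_2d, basis_2d):
        with pytest.raises(InstanceRejected):
            syn.sample_instance(template_2d, basis_2d, [500.0, 0, 0], 0.0, seed=0)


class TestPopulation:
    def test_split_sizes_floor_rule(self, template_2d, basis_2d):
        pop = syn.sample_population(
            template_2d, basis_2d, 10, 0.0, split_fractions=(0.6, 0.2, 0.2), seed=5
        )
        sizes = {k: len(v) for k, v in pop.split.items()}
        assert sizes == {"train": 6, "validation": 2, "test": 2}
        all_idx = sorted(sum(pop.split.values(), []))
        assert all_idx == list(range(10))

    def test_deterministic_and_seed_sensitive(self, template_2d, basis_2d):
        a = syn.sample_population(template_2d, basis_2d, 5, 0.02, seed=6)
        b = syn.sample_population(template_2d, basis_2d, 5, 0.02, seed=6)
        c = syn.sample_population(template_2d, basis_2d, 5, 0.02, seed=7)
        assert np.array_equal(a.landmark_matrix(), b.landmark_matrix())
        assert np.array_equal(a.appearances(), b.appearances())
        assert not np.array_equal(a.coefficients(), c.coefficients())

    def test_coefficient_means_satisfy_clt_bound(self, template_2d):
        basis = syn.build_deformation_basis(template_2d, k=2, seed=8)
        pop = syn.sample_population(template_2d, basis, 400, 0.0, seed=9)
        coeffs = pop.coefficients()
        bound = 3 * basis.amplitudes / np.sqrt(len(coeffs))
        assert np.all(np.abs(coeffs.mean(axis=0)) < bound)

    def test_roundtrip_label_invariant(self, population_2d):
        tpl = population_2d.template
        for inst in population_2d.instances[:5]:
            raster = landmarks_to_label(inst.landmarks, tpl.grid_shape, tpl.layout)
            assert np.array_equal(raster, inst.label)

    def test_validation_errors(self, template_2d, basis_2d):
        with pytest.raises(ValueError, match="n must be"):
            syn.sample_population(template_2d, basis_2d, 2, 0.0)
        with pytest.raises(ValueError, match="split_fractions"):
            syn.sample_population(
                template_2d, basis_2d, 5, 0.0, split_fractions=(0.5, 0.5, 0.5)
            )

    def test_hopeless_amplitudes_raise_after_rejections(self, template_2d):
        basis = syn.build_deformation_basis(
            template_2d, k=1, amplitudes=[1000.0], seed=10
        )
        with pytest.raises(InstanceRejected, match="amplitudes"):
            syn.sample_population(template_2d, basis, 3, 0.0, seed=11)


class TestParameterRecovery:
    def test_pca_recovers_true_mode_span(self, recovery_population):
        """PCA on landmarks of a k=3 population finds >=99% of the variance
        in 3 modes whose span matches the true modes (principal angles < 5 deg)."""
        pop = recovery_population
        X = pop.landmark_matrix()
        Xc = X - X.mean(axis=0)
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        var = s**2
        assert var[:3].sum() / var.sum() >= 0.99
        tpl = pop.template
        true_modes = np.stack(
            [
                syn._displace_landmarks(tpl.landmarks, m, 2) - tpl.landmarks
                for m in pop.basis.modes
            ]
        )
        q1, _ = np.linalg.qr(Vt[:3].T)
        q2, _ = np.linalg.qr(true_modes.T)
        cosines = np.clip(np.linalg.svd(q1.T @ q2)[1], -1.0, 1.0)
        angles = np.degrees(np.arccos(cosines))
        assert angles.max() < 5.0
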