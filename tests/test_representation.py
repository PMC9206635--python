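"""Representations, conversions, surfaces, distances and warping."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from shapearena import representation as rep
from shapearena.representation import (
    LandmarkLayout,
    assd,
    extract_surface,
    invert_displacement,
    l1_distance,
    label_to_onehot,
    landmarks_to_label,
    missing_structures,
    onehot_to_label,
    warp,
)


def brute_force_assd(a, b, structures):
    """O(n^2) all-pairs nearest-neighbor oracle for ASSD (present structures)."""
    vals = []
    for s in structures:
        sa = extract_surface(a, s)
        sb = extract_surface(b, s)
        if len(sa) == 0 or len(sb) == 0:
            continue
        d_ab = [min(np.linalg.norm(p - q) for q in sb) for p in sa]
        d_ba = [min(np.linalg.norm(p - q) for q in sa) for p in sb]
        vals.append(np.mean(d_ab + d_ba))
    return float(np.mean(vals))


def random_label_pair(rng, shape=(16, 16), n_labels=2):
    imgs = []
    for _ in range(2):
        img = np.zeros(shape, dtype=np.int64)
        for lab in range(1, n_labels + 1):
            cx, cy = rng.uniform(3, shape[0] - 3, size=2)
            r = rng.uniform(1.5, 4.0)
            xs, ys = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
            img[(xs - cx) ** 2 + (ys - cy) ** 2 <= r**2] = lab
        imgs.append(img)
    return imgs


class TestRasterization:
    def test_unit_square_fills_expected_block(self):
        square = np.array([[2.5, 2.5], [2.5, 5.5], [5.5, 5.5], [5.5, 2.5]])
        layout = LandmarkLayout(2, (1,), (4,))
        label = landmarks_to_label(square.ravel(), (8, 8), layout)
        expected = np.zeros((8, 8), dtype=np.int64)
        expected[3:6, 3:6] = 1
        assert np.array_equal(label, expected)

    def test_matches_shapely_point_in_polygon(self):
        """Random star-convex polygons agree with an independent geometric
        oracle on every pixel center."""
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import Point, Polygon

        rng = np.random.default_rng(0)
        layout = LandmarkLayout(2, (1,), (9,))
        for _ in range(25):
            angles = np.sort(rng.uniform(0, 2 * np.pi, 9))
            radii = rng.uniform(2.0, 6.5, 9)
            center = rng.uniform(6.5, 9.5, 2)
            pts = center + radii[:, None] * np.stack(
                [np.cos(angles), np.sin(angles)], axis=1
            )
            label = landmarks_to_label(pts.ravel(), (16, 16), layout)
            poly = Polygon(pts)
            for ix in range(16):
                for iy in range(16):
                    assert bool(label[ix, iy]) == poly.contains(Point(ix, iy))

    def test_priority_later_structure_wins(self):
        layout = LandmarkLayout(2, (1, 2), (4, 4))
        sq1 = np.array([[1.5, 1.5], [1.5, 8.5], [8.5, 8.5], [8.5, 1.5]])
        sq2 = sq1 + 3.0
        label = landmarks_to_label(
            np.concatenate([sq1.ravel(), sq2.ravel()]), (16, 16), layout
        )
        assert label[5, 5] == 2  # overlap voxel goes to the later structure
        assert label[2, 2] == 1

    def test_degenerate_structure_rejected(self):
        layout = LandmarkLayout(2, (1,), (2,))
        with pytest.raises(ValueError):
            landmarks_to_label(np.array([1.0, 1.0, 2.0, 2.0]), (8, 8), layout)


class TestOneHot:
    def test_roundtrip_identity(self, template_2d):
        label = template_2d.label_image
        oh = label_to_onehot(label)
        assert np.abs(oh.sum(axis=0) - 1).max() < 1e-6
        assert np.array_equal(onehot_to_label(oh), label)

    def test_tie_breaks_to_lowest_channel(self):
        oh = np.full((2, 1, 1), 0.5)
        assert onehot_to_label(oh)[0, 0] == 0

    def test_soft_prediction_matches_per_voxel_scan(self):
        rng = np.random.default_rng(1)
        soft = rng.dirichlet(np.ones(4), size=(6, 5)).transpose(2, 0, 1)
        got = onehot_to_label(soft)
        for i in range(6):
            for j in range(5):
                assert got[i, j] == int(np.argmax(soft[:, i, j]))

    def test_bad_channel_sum_rejected(self):
        oh = np.full((2, 2, 2), 0.4)
        with pytest.raises(ValueError, match="channel sums"):
            onehot_to_label(oh)


class TestSurface:
    def test_single_voxel(self):
        img = np.zeros((5, 5), dtype=np.int64)
        img[2, 3] = 1
        assert np.array_equal(extract_surface(img, 1), [[2.0, 3.0]])

    def test_filled_square_has_12_border_pixels(self):
        img = np.zeros((8, 8), dtype=np.int64)
        img[2:6, 2:6] = 1
        surf = extract_surface(img, 1)
        assert len(surf) == 12
        interior = {(3, 3), (3, 4), (4, 3), (4, 4)}
        assert not interior & {tuple(map(int, p)) for p in surf}

    def test_absent_structure_empty(self):
        assert extract_surface(np.zeros((4, 4), dtype=np.int64), 3).size == 0


class TestASSD:
    def test_identical_labels_zero(self, template_2d):
        lab = template_2d.label_image
        assert assd(lab, lab, template_2d.structures) == 0.0

    def test_shifted_square_matches_bruteforce(self):
        a = np.zeros((16, 16), dtype=np.int64)
        b = np.zeros((16, 16), dtype=np.int64)
        a[4:8, 4:8] = 1
        b[5:9, 4:8] = 1
        assert assd(a, b, [1]) == pytest.approx(brute_force_assd(a, b, [1]), abs=1e-9)

    def test_random_pairs_match_bruteforce_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            a, b = random_label_pair(rng)
            structures = [s for s in (1, 2) if (a == s).any() or (b == s).any()]
            present = [s for s in structures if (a == s).any() and (b == s).any()]
            if not present:
                continue
            got = assd(a, b, present)
            assert got == pytest.approx(brute_force_assd(a, b, present), abs=1e-9)
            assert assd(b, a, present) == pytest.approx(got, abs=1e-9)

    def test_absent_structure_policies(self):
        a = np.zeros((10, 10), dtype=np.int64)
        b = np.zeros((10, 10), dtype=np.int64)
        a[2:5, 2:5] = 1
        a[7:9, 7:9] = 2
        b[2:5, 2:5] = 1
        with pytest.warns(UserWarning, match="excluded"):
            skip = assd(a, b, [1, 2])
        assert skip == assd(a, b, [1])
        diag = assd(a, b, [1, 2], absent_policy="diagonal")
        expected_diag = np.linalg.norm([9.0, 9.0])
        assert diag == pytest.approx((assd(a, b, [1]) + expected_diag) / 2)
        with pytest.warns(UserWarning, match="absent from both"):
            both = assd(a, b, [1, 3])
        assert both == assd(a, b, [1])
        with pytest.raises(ValueError, match="no structure"):
            assd(np.zeros_like(a), np.zeros_like(b), [1])


class TestL1:
    def test_values(self):
        a = np.zeros((4, 4))
        assert l1_distance(a, a) == 0.0
        assert l1_distance(a, np.ones_like(a)) == 1.0
        rng = np.random.default_rng(3)
        x, y = rng.random((2, 5, 5))
        assert l1_distance(x, y) == pytest.approx(np.abs(x - y).mean())
        with pytest.raises(ValueError):
            l1_distance(np.zeros((2, 2)), np.zeros((3, 3)))


class TestWarp:
    def test_zero_field_is_identity(self, template_2d):
        img = template_2d.appearance_image
        field = np.zeros((2,) + img.shape)
        assert np.allclose(warp(img, field), img)
        lab = warp(template_2d.label_image, field, mode="label")
        assert np.array_equal(lab, template_2d.label_image)

    def test_uniform_shift_matches_index_shift(self):
        rng = np.random.default_rng(4)
        img = rng.random((12, 12))
        field = np.zeros((2, 12, 12))
        field[0] = 1.0  # sample from v + 1: shifts content by -1 along axis 0
        out = warp(img, field)
        assert np.allclose(out[:-1], img[1:])

    def test_label_mode_returns_valid_labels(self, population_2d):
        inst = population_2d.instances[0]
        field = population_2d.basis.field(inst.true_coefficients)
        out = warp(population_2d.template.label_image, field, mode="label")
        assert out.dtype == np.int64
        assert set(np.unique(out)) <= set(range(6))

    def test_nonfinite_field_rejected(self):
        field = np.zeros((2, 8, 8))
        field[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            warp(np.zeros((8, 8)), field)

    def test_inverse_composition_roundtrip(self):
        """Warping with a field then its numerical inverse returns a smooth
        image within interpolation tolerance."""
        rng = np.random.default_rng(5)
        img = gaussian_filter(rng.random((32, 32)), sigma=3)
        field = np.stack(
            [gaussian_filter(rng.standard_normal((32, 32)), 6) for _ in range(2)]
        )
        field *= 2.0 / np.abs(field).max()
        inv = invert_displacement(field)
        back = warp(warp(img, field), inv)
        assert np.abs(back - img).mean() < 0.05


class TestMissingStructures:
    def test_fractions(self, template_2d):
        lab = template_2d.label_image
        assert missing_structures(lab, [1, 2, 3, 4, 5]) == 0.0
        assert missing_structures(lab, [1, 2, 3, 4, 9]) == pytest.approx(0.2)
        assert missing_structures(np.zeros_like(lab), [1, 2]) == 1.0
        with pytest.raises(ValueError):
            missing_structures(lab, [])
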