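"""Synthetic multi-structure shape/appearance populations with known modes.

Desk-scale stand-in for the chest-radiograph and brain-MRI cohorts used in
generative-shape-model benchmarking: a labeled template (including
deliberately small, clavicle-like structures), k smooth ground-truth
deformation modes with Gaussian coefficients, and appearance formed as
template-plus-smooth-intensity-offset moved along with the deformation.
Because the true modes and coefficients are recorded, populations support
parameter-recovery tests (PCA should find the mode span) in addition to
serving as train/test data for every model family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .representation import (
    LandmarkLayout,
    invert_displacement,
    landmarks_to_label,
    warp,
)

__all__ = [
    "Template",
    "DeformationBasis",
    "Instance",
    "Population",
    "InstanceRejected",
    "build_template",
    "build_deformation_basis",
    "sample_instance",
    "sample_population",
]


class InstanceRejected(RuntimeError):
    """A deformed instance left the image grid; reduce the mode amplitudes."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Template:
    kind: str
    grid_shape: tuple[int, ...]
    layout: LandmarkLayout
    landmarks: np.ndarray  # flat (d*m,) vector
    label_image: np.ndarray
    appearance_image: np.ndarray
    seed: int

    @property
    def structures(self) -> tuple[int, ...]:
        return self.layout.structures


@dataclass
class DeformationBasis:
    modes: np.ndarray  # (k, d, *grid), unit-RMS displacement each
    amplitudes: np.ndarray  # (k,) per-mode standard deviations, voxels
    smoothness: float
    seed: int

    @property
    def k(self) -> int:
        return self.modes.shape[0]

    def field(self, coefficients: np.ndarray) -> np.ndarray:
        c = np.asarray(coefficients, dtype=float)
        if c.shape != (self.k,):
            raise ValueError(f"expected {self.k} coefficients, got {c.shape}")
        return np.tensordot(c, self.modes, axes=(0, 0))


@dataclass
class Instance:
    landmarks: np.ndarray
    label: np.ndarray
    appearance: np.ndarray
    true_coefficients: np.ndarray
    true_intensity_offset: np.ndarray


@dataclass
class Population:
    instances: list[Instance]
    template: Template
    basis: DeformationBasis
    split: dict[str, list[int]]
    seed: int

    def __len__(self) -> int:
        return len(self.instances)

    def indices(self, subset: str | None = None) -> list[int]:
        if subset is None:
            return list(range(len(self.instances)))
        return list(self.split[subset])

    def landmark_matrix(self, subset: str | None = None) -> np.ndarray:
        return np.stack([self.instances[i].landmarks for i in self.indices(subset)])

    def labels(self, subset: str | None = None) -> np.ndarray:
        return np.stack([self.instances[i].label for i in self.indices(subset)])

    def appearances(self, subset: str | None = None) -> np.ndarray:
        return np.stack([self.instances[i].appearance for i in self.indices(subset)])

    def coefficients(self, subset: str | None = None) -> np.ndarray:
        return np.stack(
            [self.instances[i].true_coefficients for i in self.indices(subset)]
        )


# ---------------------------------------------------------------------------
# template construction


def _equal_arclength_ellipse(
    center, axes, n_points: int, rotation: float = 0.0, wobble=None
) -> np.ndarray:
    """Points along an (optionally perturbed) ellipse at equal arc length."""
    t = np.linspace(0.0, 2 * np.pi, 2048, endpoint=False)
    r_mod = np.ones_like(t)
    if wobble is not None:
        for order, amp, phase in wobble:
            r_mod = r_mod + amp * np.cos(order * t + phase)
    x = axes[0] * r_mod * np.cos(t)
    y = axes[1] * r_mod * np.sin(t)
    if rotation:
        c, s = np.cos(rotation), np.sin(rotation)
        x, y = c * x - s * y, s * x + c * y
    pts = np.stack([x + center[0], y + center[1]], axis=1)
    seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])[:-1]
    targets = np.linspace(0.0, arc[-1] + seg[-1], n_points, endpoint=False)
    idx = np.searchsorted(arc, targets, side="right") - 1
    return pts[np.clip(idx, 0, len(pts) - 1)]


def _thorax_template(grid_shape, rng) -> tuple[LandmarkLayout, np.ndarray]:
    """Five 2D structures: two lungs, a heart, two small clavicle analogues."""
    nx, ny = grid_shape
    scale = np.array([nx, ny], dtype=float)

    def jitter(lo=-0.01, hi=0.01):
        return rng.uniform(lo, hi)

    def wob():
        return [(2, rng.uniform(0.02, 0.05), rng.uniform(0, 2 * np.pi)),
                (3, rng.uniform(0.01, 0.03), rng.uniform(0, 2 * np.pi))]

    specs = [
        # (label, center, axes, n_points, rotation)
        (1, (0.30 + jitter(), 0.45 + jitter()), (0.155, 0.250), 28, 0.12),
        (2, (0.71 + jitter(), 0.45 + jitter()), (0.155, 0.250), 28, -0.12),
        (3, (0.52 + jitter(), 0.60 + jitter()), (0.130, 0.150), 24, 0.0),
        (4, (0.30 + jitter(), 0.135 + jitter()), (0.100, 0.016), 12, 0.10),
        (5, (0.71 + jitter(), 0.135 + jitter()), (0.100, 0.016), 12, -0.10),
    ]
    parts = []
    counts = []
    for lab, center, axes, n_pts, rot in specs:
        pts = _equal_arclength_ellipse(
            np.array(center) * scale,
            np.array(axes) * scale,
            n_pts,
            rotation=rot,
            wobble=wob() if lab <= 3 else None,
        )
        parts.append(pts)
        counts.append(n_pts)
    layout = LandmarkLayout(
        ndim=2,
        structures=tuple(lab for lab, *_ in specs),
        points_per_structure=tuple(counts),
    )
    return layout, np.concatenate(parts, axis=0).ravel()


def _sphere_directions(n_theta: int, n_phi: int) -> np.ndarray:
    theta = (np.arange(n_theta) + 0.5) / n_theta * np.pi
    phi = np.arange(n_phi) / n_phi * 2 * np.pi
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    return np.stack(
        [np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp), np.cos(tt)], axis=-1
    ).reshape(-1, 3)


def _brain_template(grid_shape, rng) -> tuple[LandmarkLayout, np.ndarray]:
    """Nested 3D structures: a brain-like hull with two inner nuclei."""
    nx, ny, nz = grid_shape
    scale = np.array([nx, ny, nz], dtype=float)
    n_theta, n_phi = 6, 10
    dirs = _sphere_directions(n_theta, n_phi)

    specs = [
        (1, (0.50, 0.50, 0.50), (0.370, 0.400, 0.370)),  # hull
        (2, (0.50, 0.44, 0.52), (0.120, 0.180, 0.110)),  # ventricle-like
        (3, (0.50, 0.63, 0.44), (0.100, 0.110, 0.095)),  # nucleus-like
    ]
    parts = []
    for lab, center, axes in specs:
        c = np.array(center) * scale + rng.uniform(-0.3, 0.3, size=3)
        a = np.array(axes) * scale
        # ellipsoid radius per direction, mildly perturbed for asymmetry
        inv = np.sqrt(((dirs / a) ** 2).sum(axis=1))
        r = 1.0 / inv
        bump = 1.0 + 0.04 * np.cos(2 * np.arctan2(dirs[:, 1], dirs[:, 0]))
        r = r * bump * rng.uniform(0.98, 1.02)
        parts.append(c + r[:, None] * dirs)
    layout = LandmarkLayout(
        ndim=3,
        structures=tuple(lab for lab, *_ in specs),
        points_per_structure=tuple(dirs.shape[0] for _ in specs),
        sphere_grid=(n_theta, n_phi),
    )
    return layout, np.concatenate(parts, axis=0).ravel()


_STRUCTURE_INTENSITY = {0: 0.12, 1: 0.35, 2: 0.62, 3: 0.80, 4: 0.92, 5: 0.92}


def _render_appearance(label: np.ndarray) -> np.ndarray:
    img = np.full(label.shape, _STRUCTURE_INTENSITY[0], dtype=float)
    for lab in np.unique(label):
        if lab == 0:
            continue
        img[label == lab] = _STRUCTURE_INTENSITY.get(int(lab), 0.7)
    return np.clip(gaussian_filter(img, sigma=1.0), 0.0, 1.0)


def build_template(kind: str, grid_shape, seed: int = 0) -> Template:
    """Build a deterministic multi-structure template.

    ``"thorax-like"`` (2D) has five structures of which two have less than
    5% of the largest structure's area; ``"brain-like"`` (3D) has nested
    structures and a piecewise-constant smoothed appearance image.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if any(s < 16 for s in grid_shape):
        raise ValueError("grid_shape must be at least 16 voxels per axis")
    rng = np.random.default_rng(seed)
    if kind == "thorax-like":
        if len(grid_shape) != 2:
            raise ValueError("thorax-like templates are 2D")
        layout, landmarks = _thorax_template(grid_shape, rng)
    elif kind == "brain-like":
        if len(grid_shape) != 3:
            raise ValueError("brain-like templates are 3D")
        layout, landmarks = _brain_template(grid_shape, rng)
    else:
        raise ValueError(f"unknown template kind {kind!r}")
    label = landmarks_to_label(landmarks, grid_shape, layout)
    appearance = _render_appearance(label)
    return Template(
        kind=kind,
        grid_shape=grid_shape,
        layout=layout,
        landmarks=landmarks,
        label_image=label,
        appearance_image=appearance,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# deformation basis


def build_deformation_basis(
    template: Template,
    k: int,
    smoothness: float | None = None,
    amplitudes=None,
    seed: int = 0,
) -> DeformationBasis:
    """Generate k smooth, zero-mean, orthonormal ground-truth modes.

    Each mode is a Gaussian-smoothed random vector field, de-meaned per
    component, Gram-Schmidt-orthogonalized against the previous modes and
    normalized to unit RMS displacement, so the per-mode standard deviations
    ``amplitudes`` are in voxel units. Defaults: ``smoothness`` is an eighth
    of the smallest grid extent; amplitudes decay geometrically from 5% of
    the smallest extent, a magnitude typical of anatomical variability at
    this resolution.
    """
    d = len(template.grid_shape)
    dof = d * int(np.prod(template.grid_shape))
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > dof:
        raise ValueError(f"k={k} exceeds the {dof} grid degrees of freedom")
    if smoothness is None:
        smoothness = min(template.grid_shape) / 8.0
    if amplitudes is None:
        base = 0.05 * min(template.grid_shape)
        amplitudes = base * 0.7 ** np.arange(k)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.shape != (k,) or np.any(amplitudes <= 0):
        raise ValueError("amplitudes must be k positive values")

    rng = np.random.default_rng(seed)
    modes = []
    flat = []
    n_vals = dof
    for _ in range(k):
        raw = rng.standard_normal((d,) + template.grid_shape)
        raw = np.stack([gaussian_filter(c, sigma=smoothness) for c in raw])
        raw -= raw.mean(axis=tuple(range(1, d + 1)), keepdims=True)
        v = raw.ravel().copy()
        for u in flat:
            v -= (v @ u) * u
        norm = np.linalg.norm(v)
        if norm < 1e-10:
            raise RuntimeError("degenerate random mode; change seed or smoothness")
        u = v / norm
        flat.append(u)
        modes.append((u * np.sqrt(n_vals)).reshape((d,) + template.grid_shape))
    return DeformationBasis(
        modes=np.stack(modes),
        amplitudes=amplitudes,
        smoothness=float(smoothness),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# instances and populations


def _displace_landmarks(
    landmarks: np.ndarray, field: np.ndarray, ndim: int
) -> np.ndarray:
    pts = landmarks.reshape(-1, ndim)
    coords = pts.T  # (d, m) fractional voxel coordinates
    disp = np.stack(
        [map_coordinates(field[c], coords, order=1, mode="nearest") for c in range(ndim)],
        axis=1,
    )
    return (pts + disp).ravel()


def _smooth_offset(grid_shape, smoothness: float, offset_scale: float, rng) -> np.ndarray:
    if offset_scale == 0:
        return np.zeros(grid_shape)
    raw = gaussian_filter(rng.standard_normal(grid_shape), sigma=smoothness)
    sd = raw.std()
    if sd < 1e-12:
        return np.zeros(grid_shape)
    return offset_scale * raw / sd


def _make_instance(
    template: Template,
    basis: DeformationBasis,
    coefficients: np.ndarray,
    offset: np.ndarray,
) -> Instance:
    ndim = template.layout.ndim
    coefficients = np.asarray(coefficients, dtype=float)
    if not np.all(np.isfinite(coefficients)):
        raise ValueError("coefficients must be finite")
    phi = basis.field(coefficients)
    new_lm = _displace_landmarks(template.landmarks, phi, ndim)
    pts = new_lm.reshape(-1, ndim)
    upper = np.asarray(template.grid_shape, dtype=float) - 1.0
    if np.any(pts < 0.0) or np.any(pts > upper):
        raise InstanceRejected(
            "a displaced landmark left the grid; reduce the mode amplitudes"
        )
    label = landmarks_to_label(new_lm, template.grid_shape, template.layout)
    source = np.clip(template.appearance_image + offset, 0.0, 1.0)
    if np.any(coefficients != 0.0):
        back = invert_displacement(phi)
        appearance = warp(source, back, mode="intensity")
    else:
        appearance = source.copy()
    return Instance(
        landmarks=new_lm,
        label=label,
        appearance=appearance,
        true_coefficients=coefficients.copy(),
        true_intensity_offset=offset.copy(),
    )


def sample_instance(
    template: Template,
    basis: DeformationBasis,
    coefficients,
    offset_scale: float = 0.0,
    seed: int = 0,
) -> Instance:
    """Deform the template by the given mode coefficients.

    Landmarks are displaced by the combined field evaluated at their
    positions; the label image is the rasterization of the displaced
    landmarks; the appearance is the template plus a smooth random intensity
    offset, transported with the same deformation (backward-warped with the
    fixed-point inverse field so image content follows the landmarks).
    """
    rng = np.random.default_rng(seed)
    offset = _smooth_offset(template.grid_shape, basis.smoothness, offset_scale, rng)
    return _make_instance(template, basis, np.asarray(coefficients, float), offset)


def sample_population(
    template: Template,
    basis: DeformationBasis,
    n: int,
    offset_scale: float = 0.05,
    split_fractions=(0.5, 0.05, 0.45),
    seed: int = 0,
) -> Population:
    """Draw n instances with coefficients ``c_j ~ Normal(0, amplitude_j^2)``.

    Split sizes take the floor for train, then validation, with the
    remainder going to test; instances whose landmarks leave the grid are
    redrawn (at most 100 attempts each). The default split proportions
    mirror roughly half-train cohorts with a small validation set.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    fr = np.asarray(split_fractions, dtype=float)
    if fr.shape != (3,) or abs(fr.sum() - 1.0) > 1e-9 or np.any(fr < 0):
        raise ValueError("split_fractions must be 3 non-negative values summing to 1")
    rng = np.random.default_rng(seed)
    instances = []
    for _ in range(n):
        for attempt in range(100):
            coeffs = rng.normal(0.0, basis.amplitudes)
            offset = _smooth_offset(
                template.grid_shape, basis.smoothness, offset_scale, rng
            )
            try:
                instances.append(_make_instance(template, basis, coeffs, offset))
                break
            except InstanceRejected:
                continue
        else:
            raise InstanceRejected(
                "over 100 rejected draws for one instance; reduce the amplitudes"
            )
    n_train = int(np.floor(fr[0] * n))
    n_val = int(np.floor(fr[1] * n))
    split = {
        "train": list(range(n_train)),
        "validation": list(range(n_train, n_train + n_val)),
        "test": list(range(n_train + n_val, n)),
    }
    return Population(
        instances=instances, template=template, basis=basis, split=split, seed=seed
    )
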