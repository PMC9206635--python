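"""Shape and image representations and the distances built on them.

Conventions used throughout the package:

* Images are numpy arrays indexed ``arr[ix, iy]`` in 2D and ``arr[ix, iy, iz]``
  in 3D, so array axes coincide with the coordinate order ``(x, y[, z])`` used
  in landmark tables and files.
* Coordinates are voxel-center based and 0-indexed: the center of voxel
  ``(i, j)`` is at continuous position ``(i, j)``.
* Label images hold small non-negative integers, 0 being background.
* A landmark shape is the flat vector ``(x_1, y_1, x_2, y_2, ...)`` of all
  landmarks of all structures in a fixed order described by a
  :class:`LandmarkLayout`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

__all__ = [
    "LandmarkLayout",
    "label_to_onehot",
    "onehot_to_label",
    "landmarks_to_label",
    "extract_surface",
    "assd",
    "l1_distance",
    "warp",
    "invert_displacement",
    "missing_structures",
    "get_distance",
]


# ---------------------------------------------------------------------------
# landmark layout


@dataclass(frozen=True)
class LandmarkLayout:
    """Fixed structure/point ordering of a landmark vector.

    Parameters
    ----------
    ndim:
        Spatial dimension d (2 or 3).
    structures:
        Structure labels in rasterization priority order (later wins on
        overlap).
    points_per_structure:
        Landmark count per structure, same order as ``structures``.
    sphere_grid:
        For 3D star-convex structures, the ``(n_theta, n_phi)`` grid the
        surface landmarks were placed on. Unused in 2D.
    """

    ndim: int
    structures: tuple[int, ...]
    points_per_structure: tuple[int, ...]
    sphere_grid: tuple[int, int] | None = None

    @property
    def n_landmarks(self) -> int:
        return int(sum(self.points_per_structure))

    @property
    def vector_length(self) -> int:
        return self.ndim * self.n_landmarks

    def split(self, shape_vector: np.ndarray) -> dict[int, np.ndarray]:
        """Split a flat landmark vector into per-structure (n_i, d) arrays."""
        pts = np.asarray(shape_vector, dtype=float).reshape(-1, self.ndim)
        if pts.shape[0] != self.n_landmarks:
            raise ValueError(
                f"shape vector has {pts.shape[0]} landmarks, layout expects "
                f"{self.n_landmarks}"
            )
        out = {}
        start = 0
        for lab, n in zip(self.structures, self.points_per_structure):
            out[lab] = pts[start : start + n]
            start += n
        return out

    def join(self, per_structure: dict[int, np.ndarray]) -> np.ndarray:
        parts = [np.asarray(per_structure[lab], float) for lab in self.structures]
        return np.concatenate(parts, axis=0).ravel()


# ---------------------------------------------------------------------------
# label <-> one-hot


def label_to_onehot(label: np.ndarray, n_labels: int | None = None) -> np.ndarray:
    """One-hot encode a label image into an ``(L+1, *grid)`` float array."""
    label = np.asarray(label)
    if not np.issubdtype(label.dtype, np.integer):
        raise ValueError("label image must have an integer dtype")
    lmax = int(label.max(initial=0))
    if n_labels is None:
        n_labels = lmax
    elif lmax > n_labels:
        raise ValueError(f"label {lmax} exceeds declared maximum {n_labels}")
    oh = np.zeros((n_labels + 1,) + label.shape, dtype=float)
    for c in range(n_labels + 1):
        oh[c] = label == c
    return oh


def onehot_to_label(onehot: np.ndarray, check_sum: bool = True) -> np.ndarray:
    """Per-voxel argmax of a channel-first one-hot/soft image.

    Ties break toward the lowest channel index. Channel sums further than
    1e-3 from 1 raise, catching inputs that are not probability maps.
    """
    onehot = np.asarray(onehot, dtype=float)
    if check_sum:
        sums = onehot.sum(axis=0)
        if np.abs(sums - 1.0).max() > 1e-3:
            raise ValueError("one-hot channel sums deviate from 1 by more than 1e-3")
    return np.argmax(onehot, axis=0).astype(np.int64)


# ---------------------------------------------------------------------------
# rasterization


def _fill_polygon(vertices: np.ndarray, grid_shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of voxel centers inside a closed 2D polygon.

    Vectorized even-odd (crossing number) rule over all pixel centers.
    """
    v = np.asarray(vertices, dtype=float)
    if v.shape[0] < 3:
        raise ValueError("polygon needs at least 3 vertices")
    nx, ny = grid_shape
    xs = np.arange(nx, dtype=float)[:, None, None]  # (nx,1,1)
    ys = np.arange(ny, dtype=float)[None, :, None]  # (1,ny,1)
    x1, y1 = v[:, 0][None, None, :], v[:, 1][None, None, :]
    x2 = np.roll(v[:, 0], -1)[None, None, :]
    y2 = np.roll(v[:, 1], -1)[None, None, :]
    crosses = (y1 > ys) != (y2 > ys)
    with np.errstate(divide="ignore", invalid="ignore"):
        xint = x1 + (ys - y1) * (x2 - x1) / (y2 - y1)
    hits = crosses & (xs < xint)
    return hits.sum(axis=2) % 2 == 1


def _fill_star_convex_3d(
    points: np.ndarray, grid_shape: tuple[int, int, int], kappa: float = 60.0
) -> np.ndarray:
    """Boolean mask of voxels inside a star-convex surface point cloud.

    The boundary radius in any direction is a spherical-Gaussian-weighted
    average of the landmark radii about the landmark centroid; a voxel is
    inside iff its radius from the centroid is below that boundary radius.
    """
    pts = np.asarray(points, dtype=float)
    center = pts.mean(axis=0)
    offs = pts - center
    rad = np.linalg.norm(offs, axis=1)
    if np.any(rad < 1e-9):
        raise ValueError("degenerate landmark at structure center")
    dirs = offs / rad[:, None]  # (m, 3)

    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in grid_shape], indexing="ij")
    vox = np.stack([g.ravel() for g in grids], axis=1) - center  # (V, 3)
    vrad = np.linalg.norm(vox, axis=1)
    vdir = np.divide(vox, np.maximum(vrad, 1e-12)[:, None])
    # spherical Gaussian weights exp(kappa * (cos - 1))
    cos = vdir @ dirs.T  # (V, m)
    w = np.exp(kappa * (cos - 1.0))
    r_bound = (w * rad[None, :]).sum(axis=1) / w.sum(axis=1)
    inside = vrad <= r_bound
    return inside.reshape(grid_shape)


def landmarks_to_label(
    shape_vector: np.ndarray,
    grid_shape: tuple[int, ...],
    layout: LandmarkLayout,
) -> np.ndarray:
    """Rasterize a landmark shape into a label image.

    Structures are filled in the layout's listed order, so a later structure
    overwrites earlier ones on overlapping voxels (priority rule). 2D
    structures are closed polygons in boundary order; 3D structures are
    star-convex surfaces.
    """
    per = layout.split(shape_vector)
    label = np.zeros(grid_shape, dtype=np.int64)
    for lab in layout.structures:
        pts = per[lab]
        if pts.shape[0] < 3:
            raise ValueError(f"structure {lab} has fewer than 3 landmarks")
        if layout.ndim == 2:
            mask = _fill_polygon(pts, grid_shape)  # type: ignore[arg-type]
        else:
            mask = _fill_star_convex_3d(pts, grid_shape)  # type: ignore[arg-type]
        label[mask] = lab
    return label


# ---------------------------------------------------------------------------
# surfaces and distances


def extract_surface(label: np.ndarray, structure: int) -> np.ndarray:
    """Voxel-center coordinates of the boundary of one structure.

    A structure voxel is a surface voxel if at least one face-adjacent
    neighbor (4-connectivity in 2D, 6 in 3D) carries a different label or
    lies outside the grid. Returns an ``(n, d)`` array (empty if absent).
    """
    label = np.asarray(label)
    mask = label == structure
    if not mask.any():
        return np.zeros((0, label.ndim))
    border = np.zeros_like(mask)
    for ax in range(label.ndim):
        for shift in (1, -1):
            rolled = np.roll(mask, shift, axis=ax)
            # voxels rolled in from the opposite edge count as outside
            edge = [slice(None)] * label.ndim
            edge[ax] = 0 if shift == 1 else -1
            rolled[tuple(edge)] = False
            border |= mask & ~rolled
    return np.argwhere(border).astype(float)


def _grid_diagonal(grid_shape: tuple[int, ...], spacing) -> float:
    sp = np.broadcast_to(np.asarray(spacing, float), (len(grid_shape),))
    return float(np.linalg.norm((np.asarray(grid_shape) - 1) * sp))


def assd(
    a: np.ndarray,
    b: np.ndarray,
    structures,
    spacing: float | tuple[float, ...] = 1.0,
    absent_policy: str = "skip",
) -> float:
    """Average symmetric surface distance between two label images.

    For each structure the mean of nearest-neighbor distances from every
    surface point of ``a`` to the surface of ``b`` and vice versa is taken;
    the result is averaged over structures. A structure absent from both
    images is skipped with a warning. A structure absent from exactly one
    image has no surface to measure against: with the default
    ``absent_policy="skip"`` it is excluded from the average and flagged
    (the omission is what :func:`missing_structures` reports separately);
    ``absent_policy="diagonal"`` instead charges the grid diagonal as a
    finite worst-case penalty.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label images must share a grid")
    sp = np.broadcast_to(np.asarray(spacing, float), (a.ndim,))
    per_structure = []
    one_sided = 0
    for s in structures:
        sa = extract_surface(a, s) * sp
        sb = extract_surface(b, s) * sp
        if len(sa) == 0 and len(sb) == 0:
            warnings.warn(f"structure {s} absent from both images; skipped")
            continue
        if len(sa) == 0 or len(sb) == 0:
            one_sided += 1
            if absent_policy == "diagonal":
                per_structure.append(_grid_diagonal(a.shape, spacing))
            else:
                warnings.warn(
                    f"structure {s} absent from one image; excluded from ASSD"
                )
            continue
        d_ab = cKDTree(sb).query(sa)[0]
        d_ba = cKDTree(sa).query(sb)[0]
        per_structure.append(float(np.concatenate([d_ab, d_ba]).mean()))
    if not per_structure:
        if one_sided:
            # no structure was measurable in both images: total mismatch
            return _grid_diagonal(a.shape, spacing)
        raise ValueError("no structure present in either image")
    return float(np.mean(per_structure))


def l1_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Mean absolute intensity difference between two images."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a grid")
    return float(np.abs(a - b).mean())


def get_distance(name: str):
    """Look up an image-wise distance by name.

    ``"assd"`` closes over no structure list; the caller supplies label
    images and the structure labels via ``functools.partial`` where needed.
    """
    if name == "l1":
        return l1_distance
    if name == "assd":
        return assd
    raise KeyError(f"unknown distance {name!r}")


# ---------------------------------------------------------------------------
# warping


def _sample_positions(grid_shape: tuple[int, ...], field: np.ndarray) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in grid_shape], indexing="ij")
    return np.stack(grids, axis=0) + field


def warp(image: np.ndarray, field: np.ndarray, mode: str = "intensity") -> np.ndarray:
    """Backward-warp an image with a displacement field.

    ``out(v) = image(v + field(v))`` with linear interpolation and edge
    clamping. ``mode="label"`` one-hot encodes, warps each channel linearly
    and takes the per-voxel argmax, which keeps boundaries smoother than
    nearest-neighbor resampling.
    """
    image = np.asarray(image)
    field = np.asarray(field, dtype=float)
    if not np.all(np.isfinite(field)):
        raise ValueError("displacement field contains non-finite values")
    if field.shape != (image.ndim,) + image.shape:
        raise ValueError("field must have one channel per image axis on the image grid")
    coords = _sample_positions(image.shape, field)
    if mode == "intensity":
        return map_coordinates(
            np.asarray(image, float), coords, order=1, mode="nearest"
        )
    if mode == "label":
        oh = label_to_onehot(image)
        warped = np.stack(
            [map_coordinates(c, coords, order=1, mode="nearest") for c in oh]
        )
        return np.argmax(warped, axis=0).astype(np.int64)
    raise ValueError(f"unknown warp mode {mode!r}")


def invert_displacement(
    field: np.ndarray, n_iter: int = 20, tol: float = 0.01
) -> np.ndarray:
    """Fixed-point inverse of a displacement field.

    Solves ``inv(v) = -field(v + inv(v))`` so that warping with ``inv``
    undoes (to interpolation tolerance) warping with ``field``. Iteration
    stops early once the mean update drops below ``tol`` voxels.
    """
    field = np.asarray(field, dtype=float)
    inv = np.zeros_like(field)
    grid_shape = field.shape[1:]
    for _ in range(n_iter):
        coords = _sample_positions(grid_shape, inv)
        sampled = np.stack(
            [map_coordinates(f, coords, order=1, mode="nearest") for f in field]
        )
        new = -sampled
        step = float(np.abs(new - inv).mean())
        inv = new
        if step < tol:
            break
    return inv


def missing_structures(label: np.ndarray, expected_structures) -> float:
    """Fraction of expected structures with zero voxels in a label image."""
    expected = list(expected_structures)
    if not expected:
        raise ValueError("expected_structures must be non-empty")
    label = np.asarray(label)
    absent = sum(1 for s in expected if not np.any(label == s))
    return absent / len(expected)
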