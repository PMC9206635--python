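"""PCA-based statistical shape and appearance models.

The classical shape model is a PCA of corresponded landmark vectors: a mean
shape ``x_mu`` plus an orthonormal basis ``U`` so that ``x = x_mu + U z``.
The locality-based variant attenuates the sample covariance by a
compactly-supported kernel of inter-landmark distance at several resolution
levels and accumulates each level's leading eigenmodes into one orthonormal
basis, trading compactness for flexibility on small training sets. The
appearance model adds a second PCA over images warped into the mean-shape
frame ("shape-normalized" intensities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RBFInterpolator
from sklearn.base import BaseEstimator
from sklearn.utils import check_random_state

from .representation import warp

__all__ = [
    "StatisticalShapeModel",
    "LocalityShapeModel",
    "StatisticalAppearanceModel",
    "LocalitySchedule",
    "wendland_taper",
    "fit_ssm",
    "fit_lssm",
    "fit_sam",
    "project",
    "reconstruct",
    "sample_ssm",
]

_EIG_FLOOR = 1e-12


def wendland_taper(r: np.ndarray) -> np.ndarray:
    """Wendland C2 compactly supported kernel; 1 at 0, 0 beyond r=1."""
    r = np.asarray(r, dtype=float)
    out = np.where(r < 1.0, (1.0 - r) ** 4 * (4.0 * r + 1.0), 0.0)
    return out


@dataclass
class LocalitySchedule:
    """Distance radii (largest first; ``inf`` means no attenuation) and taper."""

    levels: tuple[float, ...]
    taper: object = wendland_taper

    def __post_init__(self):
        lv = tuple(float(r) for r in self.levels)
        if any(b >= a for a, b in zip(lv, lv[1:])):
            raise ValueError("radii must be strictly decreasing")
        self.levels = lv


class StatisticalShapeModel(BaseEstimator):
    """Linear point-distribution model fit by PCA.

    Parameters
    ----------
    variability_threshold:
        Fraction of total variance the retained modes must explain; the
        latent dimension ``n_components_`` is the smallest number of leading
        modes reaching it (default 0.95).

    Attributes
    ----------
    mean_ : (dm,) mean shape vector.
    components_ : (p, dm) orthonormal mode matrix (rows are modes).
    mode_variances_ : (p,) eigenvalues of the retained modes, non-increasing.
    latent_mean_, latent_sd_ : per-dimension statistics of the training
        latents, used by :meth:`sample` for the fairness sampling protocol.
    """

    def __init__(self, variability_threshold: float = 0.95):
        self.variability_threshold = variability_threshold

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_samples, dm)")
        n, dm = X.shape
        if n < 2:
            raise ValueError("need at least 2 training shapes")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        # economy SVD == N x N Gram-trick eigendecomposition for dm >> N
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        variances = s**2 / (n - 1)
        rank = int(np.sum(variances > _EIG_FLOOR))
        if rank == 0:
            warnings.warn("all training shapes identical; model has 0 modes")
            p = 0
        else:
            total = variances[:rank].sum()
            cum = np.cumsum(variances[:rank]) / total
            p = int(np.searchsorted(cum, self.variability_threshold - 1e-12) + 1)
            p = min(p, rank)
        self.components_ = Vt[:p]
        self.mode_variances_ = variances[:p]
        self.n_components_ = p
        self.n_features_in_ = dm
        Z = self.transform(X)
        self.latent_mean_ = Z.mean(axis=0)
        self.latent_sd_ = Z.std(axis=0)
        return self

    def _check_fitted(self):
        if not hasattr(self, "components_"):
            raise RuntimeError("model is not fitted")

    # -- generative contract ---------------------------------------------
    def transform(self, X) -> np.ndarray:
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("shape vector length mismatch")
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, Z) -> np.ndarray:
        self._check_fitted()
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[1] != self.n_components_:
            raise ValueError("latent vector length mismatch")
        return self.mean_ + Z @ self.components_

    def encode(self, x) -> np.ndarray:
        return self.transform(np.atleast_2d(x))[0] if np.ndim(x) == 1 else self.transform(x)

    def decode(self, z) -> np.ndarray:
        return self.inverse_transform(np.atleast_2d(z))[0] if np.ndim(z) == 1 else self.inverse_transform(z)

    def reconstruct(self, X) -> np.ndarray:
        one = np.ndim(X) == 1
        out = self.inverse_transform(self.transform(np.atleast_2d(X)))
        return out[0] if one else out

    def sample(self, n: int, random_state=None, latent_stats=None) -> np.ndarray:
        """Draw shapes with ``z ~ Normal(latent mean, latent sd)`` per dim."""
        self._check_fitted()
        if n <= 0:
            raise ValueError("n must be positive")
        if latent_stats is None:
            mean, sd = self.latent_mean_, self.latent_sd_
        else:
            mean, sd = (np.asarray(a, dtype=float) for a in latent_stats)
        rng = np.random.default_rng(
            random_state if not hasattr(random_state, "normal") else None
        )
        if hasattr(random_state, "normal"):
            rng = random_state
        Z = rng.normal(mean, sd, size=(n, self.n_components_))
        return self.inverse_transform(Z)


class LocalityShapeModel(StatisticalShapeModel):
    """Locality-based shape model with distance-tapered covariances.

    For each level radius ``r`` (coarse to fine, ``inf`` = plain PCA), the
    sample covariance is attenuated elementwise by ``taper(d_ij / r)`` of
    the mean-shape landmark distances; each level's leading eigenmodes
    (per-level 95% variance cut) are Gram-Schmidt-orthogonalized against
    the modes kept so far. The default schedule opens with a global level,
    so the plain model's subspace is always contained and the accumulated
    latent dimension is at least the plain model's.
    """

    def __init__(
        self,
        variability_threshold: float = 0.95,
        schedule: LocalitySchedule | None = None,
        ndim: int = 2,
        per_level_threshold: float = 0.95,
    ):
        super().__init__(variability_threshold)
        self.schedule = schedule
        self.ndim = ndim
        self.per_level_threshold = per_level_threshold

    def _default_schedule(self, positions: np.ndarray) -> LocalitySchedule:
        diag = float(np.linalg.norm(positions.max(0) - positions.min(0)))
        return LocalitySchedule(levels=(np.inf, diag / 2.0, diag / 4.0))

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, dm = X.shape
        if n < 2:
            raise ValueError("need at least 2 training shapes")
        if dm % self.ndim:
            raise ValueError("shape vector length not divisible by ndim")
        self.mean_ = X.mean(axis=0)
        self.n_features_in_ = dm
        positions = self.mean_.reshape(-1, self.ndim)
        schedule = self.schedule or self._default_schedule(positions)
        if not schedule.levels:
            warnings.warn("empty locality schedule; falling back to plain PCA")
            return StatisticalShapeModel.fit(self, X)

        Xc = X - self.mean_
        C = Xc.T @ Xc / (n - 1)
        D = np.linalg.norm(positions[:, None] - positions[None, :], axis=-1)
        kept: list[np.ndarray] = []
        kept_var: list[float] = []
        for radius in schedule.levels:
            if np.isinf(radius):
                T = np.ones_like(C)
            else:
                t_lm = np.asarray(schedule.taper(D / radius), dtype=float)
                T = np.kron(t_lm, np.ones((self.ndim, self.ndim)))
            w, V = np.linalg.eigh(C * T)
            order = np.argsort(w)[::-1]
            w, V = w[order], V[:, order]
            valid = w > _EIG_FLOOR
            w, V = w[valid], V[:, valid]
            if w.size == 0:
                continue
            cum = np.cumsum(w) / w.sum()
            p_level = int(np.searchsorted(cum, self.per_level_threshold - 1e-12) + 1)
            for j in range(min(p_level, w.size)):
                v = V[:, j].copy()
                for u in kept:
                    v -= (v @ u) * u
                norm = np.linalg.norm(v)
                if norm > 1e-8:
                    kept.append(v / norm)
                    kept_var.append(float(w[j]))
        self.components_ = np.stack(kept) if kept else np.zeros((0, dm))
        self.mode_variances_ = np.asarray(kept_var)
        self.n_components_ = len(kept)
        self.schedule_ = schedule
        Z = self.transform(X)
        self.latent_mean_ = Z.mean(axis=0)
        self.latent_sd_ = Z.std(axis=0)
        return self


class StatisticalAppearanceModel(BaseEstimator):
    """Shape PCA plus PCA of shape-normalized intensities.

    Training images are warped into the mean-shape frame using scattered
    thin-plate-spline interpolation of the landmark displacements; the
    intensity PCA is taken there. Generation draws shape and appearance
    latents independently and warps the decoded mean-frame image onto the
    decoded shape.
    """

    def __init__(
        self,
        variability_threshold: float = 0.95,
        appearance_threshold: float = 0.95,
        ndim: int = 2,
        grid_shape: tuple[int, ...] | None = None,
        locality: bool = False,
    ):
        self.variability_threshold = variability_threshold
        self.appearance_threshold = appearance_threshold
        self.ndim = ndim
        self.grid_shape = grid_shape
        self.locality = locality

    # -- warping helpers --------------------------------------------------
    def _field_from_landmarks(self, src_pts, dst_pts) -> np.ndarray:
        """Dense backward field u with ``u(src) = dst - src`` (TPS-style)."""
        grid = np.stack(
            np.meshgrid(*[np.arange(s, dtype=float) for s in self.grid_shape_],
                        indexing="ij"),
            axis=-1,
        ).reshape(-1, self.ndim)
        rbf = RBFInterpolator(
            src_pts, dst_pts - src_pts, kernel="thin_plate_spline", smoothing=1e-10
        )
        disp = rbf(grid)
        return disp.T.reshape((self.ndim,) + self.grid_shape_)

    def to_mean_frame(self, shape_vec: np.ndarray, image: np.ndarray) -> np.ndarray:
        pts = np.asarray(shape_vec, float).reshape(-1, self.ndim)
        field = self._field_from_landmarks(self.mean_points_, pts)
        return warp(image, field, mode="intensity")

    def from_mean_frame(self, shape_vec: np.ndarray, image: np.ndarray) -> np.ndarray:
        pts = np.asarray(shape_vec, float).reshape(-1, self.ndim)
        field = self._field_from_landmarks(pts, self.mean_points_)
        return warp(image, field, mode="intensity")

    # -- fitting ----------------------------------------------------------
    def fit(self, X, A):
        X = np.asarray(X, dtype=float)
        A = np.asarray(A, dtype=float)
        if len(X) != len(A):
            raise ValueError("need paired shapes and appearance images")
        self.grid_shape_ = self.grid_shape or A.shape[1:]
        if self.locality:
            self.shape_model_ = LocalityShapeModel(
                self.variability_threshold, ndim=self.ndim
            ).fit(X)
        else:
            self.shape_model_ = StatisticalShapeModel(self.variability_threshold).fit(X)
        self.mean_points_ = self.shape_model_.mean_.reshape(-1, self.ndim)
        normalized = []
        for x, a in zip(X, A):
            try:
                normalized.append(self.to_mean_frame(x, a).ravel())
            except np.linalg.LinAlgError:
                warnings.warn("non-invertible warp; training instance skipped")
        self.appearance_model_ = StatisticalShapeModel(self.appearance_threshold).fit(
            np.stack(normalized)
        )
        self.n_components_ = (
            self.shape_model_.n_components_,
            self.appearance_model_.n_components_,
        )
        return self

    def _check_fitted(self):
        if not hasattr(self, "shape_model_"):
            raise RuntimeError("model is not fitted")

    # -- generative contract ---------------------------------------------
    def encode(self, item) -> np.ndarray:
        """Encode a ``(shape_vector, appearance_image)`` pair."""
        self._check_fitted()
        shape_vec, image = item
        z_s = self.shape_model_.encode(np.asarray(shape_vec, float))
        z_a = self.appearance_model_.encode(self.to_mean_frame(shape_vec, image).ravel())
        return np.concatenate([z_s, z_a])

    def decode(self, z) -> tuple[np.ndarray, np.ndarray]:
        self._check_fitted()
        p_s = self.shape_model_.n_components_
        z = np.asarray(z, dtype=float)
        shape_vec = self.shape_model_.decode(z[:p_s])
        mean_frame = self.appearance_model_.decode(z[p_s:]).reshape(self.grid_shape_)
        return shape_vec, self.from_mean_frame(shape_vec, mean_frame)

    def reconstruct(self, item) -> tuple[np.ndarray, np.ndarray]:
        return self.decode(self.encode(item))

    def sample(self, n: int, random_state=None) -> list[tuple[np.ndarray, np.ndarray]]:
        """Independent shape and appearance latent draws, warped back."""
        self._check_fitted()
        rng = check_random_state(random_state)
        rng = np.random.default_rng(rng.randint(2**31))
        shapes = self.shape_model_.sample(n, random_state=rng)
        zs_a = rng.normal(
            self.appearance_model_.latent_mean_,
            self.appearance_model_.latent_sd_,
            size=(n, self.appearance_model_.n_components_),
        )
        out = []
        for i in range(n):
            mean_frame = self.appearance_model_.decode(zs_a[i]).reshape(self.grid_shape_)
            out.append((shapes[i], self.from_mean_frame(shapes[i], mean_frame)))
        return out


# ---------------------------------------------------------------------------
# thin functional wrappers


def fit_ssm(shapes, variability_threshold: float = 0.95) -> StatisticalShapeModel:
    return StatisticalShapeModel(variability_threshold).fit(np.asarray(shapes, float))


def fit_lssm(
    shapes,
    schedule: LocalitySchedule | None = None,
    variability_threshold: float = 0.95,
    ndim: int = 2,
) -> StatisticalShapeModel:
    if schedule is not None and not schedule.levels:
        warnings.warn("empty locality schedule; fitting a plain shape model")
        return fit_ssm(shapes, variability_threshold)
    return LocalityShapeModel(
        variability_threshold, schedule=schedule, ndim=ndim
    ).fit(np.asarray(shapes, float))


def fit_sam(
    shapes, appearances, variability_threshold: float = 0.95, ndim: int = 2
) -> StatisticalAppearanceModel:
    return StatisticalAppearanceModel(
        variability_threshold, ndim=ndim
    ).fit(shapes, appearances)


def project(model: StatisticalShapeModel, shape) -> np.ndarray:
    return model.encode(shape)


def reconstruct(model: StatisticalShapeModel, z) -> np.ndarray:
    return model.decode(z)


def sample_ssm(model: StatisticalShapeModel, n: int, latent_stats=None, seed=None):
    return model.sample(n, random_state=seed, latent_stats=latent_stats)
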