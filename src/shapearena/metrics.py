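"""Evaluation metrics for generative shape/appearance models.

All metrics are model-agnostic: they only require the generative contract
(``encode``, ``decode``, ``reconstruct``, ``sample``) plus an image-wise
distance function, so statistical and neural models are measured by
identical code paths.

* Generalization ability (GA): mean distance between held-out images and
  their reconstructions — can the model represent unseen samples?
* Specificity: mean distance from generated samples to their best-fitting
  real image — does the model only generate realistic samples?
* Likeness (DSI): distance-based separability of the real and synthetic
  sets — the average of two Kolmogorov-Smirnov statistics comparing the
  within-set distance distributions to the between-set one; in [0, 1],
  smaller meaning the synthetic set is statistically indistinguishable.
* Normality: percentage of latent dimensions a Shapiro-Wilk test rejects
  as non-normal when encoding real samples.
* Latent ambiguity score (LAS): mean latent shift under
  encode-decode-re-encode, normalized by the mean pairwise encoded
  distance; 0 means reconstructions map back to their own codes (true for
  any linear PCA model), values near 1 mean re-encodings land at random.
* Compactness: the latent dimensionality (number of PCA modes at the
  variability threshold, or a network's configured latent size).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MetricReport",
    "generalization_ability",
    "specificity",
    "ks_statistic",
    "likeness_dsi",
    "normality_fraction",
    "latent_ambiguity_score",
    "compactness",
]


@dataclass
class MetricReport:
    """One evaluated (model, training size, fold) cell."""

    model: str
    train_size: int
    fold: int
    ga: float = np.nan
    specificity: float = np.nan
    likeness: float = np.nan
    las: float = np.nan
    normality_pct: float = np.nan
    compactness: object = None
    missing_pct: float = np.nan
    failed: bool = False

    def to_dict(self) -> dict:
        d = dict(vars(self))
        if isinstance(d["compactness"], tuple):
            d["compactness"] = "+".join(str(c) for c in d["compactness"])
        return d


def _identity(x):
    return x


def generalization_ability(model, held_out, dist, as_image=_identity) -> float:
    """Mean distance between held-out items and their reconstructions."""
    items = list(held_out)
    if not items:
        raise ValueError("held-out set is empty")
    return float(
        np.mean([dist(as_image(r), model.reconstruct(r)) for r in items])
    )


def specificity(model, real, n_samples: int, dist, seed=None,
                as_image=_identity) -> float:
    """Mean distance from each generated sample to its closest real image."""
    real_imgs = [as_image(r) for r in real]
    if not real_imgs:
        raise ValueError("real set is empty")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    samples = model.sample(n_samples, random_state=seed)
    return float(
        np.mean([min(dist(r, s) for r in real_imgs) for s in samples])
    )


def ks_statistic(a, b) -> float:
    """Two-sample Kolmogorov-Smirnov statistic (sup of ECDF difference)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(stats.ks_2samp(a, b).statistic)


def _pair_distances(items, dist, rng=None, max_pairs: int = 20000):
    """Distances over unordered distinct pairs, seeded subsample if huge."""
    n = len(items)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if len(pairs) > max_pairs and rng is not None:
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in idx]
    return np.array([dist(items[i], items[j]) for i, j in pairs])


def likeness_dsi(real, synth, dist, seed: int = 0) -> float:
    """Distance-based separability index between real and synthetic sets.

    ``DSI = (KS({d_R}, {d_RS}) + KS({d_S}, {d_RS})) / 2`` where {d_R} and
    {d_S} are the intra-class distance sets over unordered distinct pairs
    and {d_RS} the between-class distances over all cross pairs. For sets
    with more than 200 items, pairs are subsampled with a fixed seed.
    """
    real = list(real)
    synth = list(synth)
    if len(real) < 2 or len(synth) < 2:
        raise ValueError("need at least 2 items per set")
    rng = np.random.default_rng(seed)
    sub = rng if max(len(real), len(synth)) > 200 else None
    d_r = _pair_distances(real, dist, sub)
    d_s = _pair_distances(synth, dist, sub)
    cross = [(i, j) for i in range(len(real)) for j in range(len(synth))]
    if sub is not None and len(cross) > 20000:
        idx = sub.choice(len(cross), size=20000, replace=False)
        cross = [cross[i] for i in idx]
    d_rs = np.array([dist(real[i], synth[j]) for i, j in cross])
    return 0.5 * (ks_statistic(d_r, d_rs) + ks_statistic(d_s, d_rs))


def normality_fraction(latents, alpha: float = 0.05) -> float:
    """Percentage of latent dimensions rejected as non-normal.

    Shapiro-Wilk per dimension at level ``alpha``; constant dimensions
    cannot come from a continuous normal and count as rejected.
    """
    Z = np.atleast_2d(np.asarray(latents, dtype=float))
    n, p = Z.shape
    if n < 8:
        raise ValueError("need at least 8 samples for a meaningful test")
    rejected = 0
    for j in range(p):
        col = Z[:, j]
        if np.ptp(col) < 1e-12:
            warnings.warn(f"latent dimension {j} is constant; counted non-normal")
            rejected += 1
            continue
        if stats.shapiro(col).pvalue < alpha:
            rejected += 1
    return 100.0 * rejected / p


def latent_ambiguity_score(model, real) -> float:
    """Mean re-encoding drift over mean pairwise encoded distance.

    ``LAS = mean_i ||f(r_i) - f(g(f(r_i)))|| / mean_{i != j} ||f(r_i) - f(r_j)||``.
    """
    items = list(real)
    if len(items) < 2:
        raise ValueError("need at least 2 real images")
    reencode = getattr(model, "reencode", None) or (
        lambda z: model.encode(model.decode(z))
    )
    codes = np.stack([np.asarray(model.encode(r), dtype=float) for r in items])
    recode = np.stack([np.asarray(reencode(z), dtype=float) for z in codes])
    drift = np.linalg.norm(codes - recode, axis=1).mean()
    pair = np.linalg.norm(codes[:, None] - codes[None, :], axis=-1)
    n = len(items)
    base = pair.sum() / (n * (n - 1))
    if base == 0:
        raise ValueError("all encodings identical; LAS undefined")
    return float(drift / base)


def compactness(model):
    """Latent dimensionality of a fitted model.

    PCA models report the number of retained modes; networks report their
    configured latent size (shape+appearance split models report a pair).
    """
    if hasattr(model, "n_components_"):
        return model.n_components_
    if hasattr(model, "latent_dim"):
        return model.latent_dim
    raise TypeError("model exposes neither n_components_ nor latent_dim")
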