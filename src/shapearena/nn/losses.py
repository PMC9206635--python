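"""Training losses: generalized Dice, SSIM, KL, adversarial, field regularizer.

All losses accept either autograd :class:`~shapearena.nn.autograd.Tensor`
inputs (returning a scalar Tensor for backpropagation) or plain numpy arrays
(returning a float), so the same code serves training and oracle testing.

Array inputs are channel-first. Rank conventions: a rank-3 array is a single
2D image ``(C, H, W)``; a rank-5 array is a batch of 3D images; a rank-4
array is ambiguous and is read as a 2D batch ``(B, C, H, W)`` unless
``batched=False`` is passed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, box_filter

__all__ = [
    "generalized_dice_loss",
    "ssim_loss",
    "kl_loss",
    "adversarial_losses",
    "displacement_regularizer",
]

_EPS = 1e-6


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def _maybe_float(out, *inputs):
    if any(isinstance(i, Tensor) for i in inputs):
        return out
    return float(out.data)


def _ensure_batched(x: Tensor, batched) -> Tensor:
    if x.ndim == 3:
        batched = False
    elif x.ndim == 5:
        batched = True
    elif batched is None:
        batched = True
    if not batched:
        x = x.reshape((1,) + x.shape)
    return x


def generalized_dice_loss(pred, target, weights=None, batched=None):
    """1 minus the weighted generalized Dice overlap of two soft one-hots.

    Per-class weights default to the inverse squared class volume of the
    target (classes absent from the target get weight 0 so they cannot
    dominate). Result lies in [0, 1] and is 0 for identical one-hot maps.
    """
    p_raw, t_raw = pred, target
    p = _as_tensor(pred)
    t = _as_tensor(target)
    if p.shape != t.shape:
        raise ValueError("pred and target must have the same shape")
    p = _ensure_batched(p, batched)
    t = _ensure_batched(t, batched)
    reduce_axes = (0,) + tuple(range(2, p.ndim))
    t_vol = t.data.sum(axis=reduce_axes)
    if weights is None:
        w = np.where(t_vol > 0, 1.0 / np.maximum(t_vol, _EPS) ** 2, 0.0)
    else:
        w = np.asarray(weights, dtype=float)
    if np.all(w == 0):
        raise ValueError("all class weights are zero")
    intersect = (p * t).sum(axis=reduce_axes)
    total = p.sum(axis=reduce_axes) + t.sum(axis=reduce_axes)
    w_t = Tensor(w)
    num = (w_t * intersect).sum() * 2.0
    den = (w_t * total).sum() + _EPS
    out = 1.0 - num / den
    return _maybe_float(out, p_raw, t_raw)


def ssim_loss(pred, target, window: int = 7, c1: float = 0.01**2,
              c2: float = 0.03**2, batched=None):
    """1 minus mean local SSIM (box window 7, standard constants, range 1).

    Single-channel rank-2 (one 2D image) and rank-3 inputs are promoted to
    a one-image, one-channel batch.
    """
    p_raw, t_raw = pred, target
    p = _as_tensor(pred)
    t = _as_tensor(target)
    if p.shape != t.shape:
        raise ValueError("pred and target must have the same shape")
    if not (np.all(np.isfinite(p.data)) and np.all(np.isfinite(t.data))):
        raise ValueError("non-finite input to ssim_loss")
    if p.ndim == 2 or (p.ndim == 3 and batched is None):
        # a bare 2D or 3D intensity image without batch/channel axes
        p = p.reshape((1, 1) + p.shape)
        t = t.reshape((1, 1) + t.shape)
    else:
        p = _ensure_batched(p, batched)
        t = _ensure_batched(t, batched)
    mu_p = box_filter(p, window)
    mu_t = box_filter(t, window)
    var_p = box_filter(p * p, window) - mu_p * mu_p
    var_t = box_filter(t * t, window) - mu_t * mu_t
    cov = box_filter(p * t, window) - mu_p * mu_t
    ssim_map = ((mu_p * mu_t * 2.0 + c1) * (cov * 2.0 + c2)) / (
        (mu_p * mu_p + mu_t * mu_t + c1) * (var_p + var_t + c2)
    )
    out = 1.0 - ssim_map.mean()
    return _maybe_float(out, p_raw, t_raw)


def kl_loss(mu, logvar):
    """KL divergence of N(mu, exp(logvar)) from N(0, 1), mean over batch.

    Per sample the closed form 0.5 * sum(mu^2 + sigma^2 - 1 - log sigma^2)
    is summed over latent dimensions.
    """
    m_raw, l_raw = mu, logvar
    m = _as_tensor(mu)
    lv = _as_tensor(logvar)
    if m.ndim <= 1:
        m = m.reshape((1, -1))
        lv = lv.reshape((1, -1))
    per_sample = ((m * m) + lv.exp() - 1.0 - lv).sum(axis=1) * 0.5
    return _maybe_float(per_sample.mean(), m_raw, l_raw)


def adversarial_losses(disc_out_real, disc_out_fake, eps: float = 1e-7):
    """Binary cross-entropy GAN losses from discriminator probabilities.

    Returns ``(gen_term, disc_term)``: the non-saturating generator loss
    ``-E[log d(fake)]`` and the discriminator loss
    ``-(E[log d(real)] + E[log(1 - d(fake))])``.
    """
    r_raw, f_raw = disc_out_real, disc_out_fake
    if not (np.all(np.isfinite(_as_tensor(r_raw).data))
            and np.all(np.isfinite(_as_tensor(f_raw).data))):
        raise ValueError("non-finite discriminator outputs")
    r = _as_tensor(disc_out_real).clamp(eps, 1.0 - eps)
    f = _as_tensor(disc_out_fake).clamp(eps, 1.0 - eps)
    gen = -(f.log().mean())
    disc = -(r.log().mean() + (1.0 - f).log().mean())
    if isinstance(r_raw, Tensor) or isinstance(f_raw, Tensor):
        return gen, disc
    return float(gen.data), float(disc.data)


def displacement_regularizer(field, weight: float = 10.0, batched=None):
    """Diffusion plus L1 penalty on a displacement field, both weighted.

    ``weight * mean_v(sum over channels and axes of squared forward
    differences) + weight * mean_v(sum over channels of |u|)``. Zero for
    the zero field; the diffusion term vanishes for any constant field. A
    rank-3 input is a single 2D field ``(2, H, W)``; rank-5 a 3D batch;
    rank-4 a 2D batch unless ``batched=False`` (single 3D field).
    """
    f_raw = field
    f = _as_tensor(field)
    f = _ensure_batched(f, batched)
    spatial_axes = tuple(range(2, f.ndim))
    diffusion = Tensor(0.0)
    for ax in spatial_axes:
        n = f.shape[ax]
        hi = [slice(None)] * f.ndim
        lo = [slice(None)] * f.ndim
        hi[ax] = slice(1, n)
        lo[ax] = slice(0, n - 1)
        diff = f[tuple(hi)] - f[tuple(lo)]
        diffusion = diffusion + (diff * diff).sum(axis=1).mean()
    l1 = f.abs().sum(axis=1).mean()
    out = diffusion * weight + l1 * weight
    return _maybe_float(out, f_raw)
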