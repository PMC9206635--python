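"""Convolutional generative models: AE, VAE, AE-GAN, DAE and ADAE.

All five families share one fixed architecture so that differences in the
comparison reflect the modeling principle, not architecture search: the
encoder is three stride-2 convolutions with channels [in, 20, 40, 80]
followed by a fully connected layer to the latent vector; decoders mirror
it with linear (bi-/trilinear) upsampling and convolutions with channels
[80, 40, 20, out]. Label inputs are one-hot encoded and trained with a
weighted generalized Dice loss; intensity inputs use an SSIM loss. The
template-deformation models (DAE/ADAE) decode a displacement field that
warps a fixed template (ADAE additionally decodes a per-image intensity
offset added to the template before warping), with the field under
diffusion + L1 regularization, both weighted by 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .nn.autograd import Tensor, warp_channels
from .representation import label_to_onehot

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "Autoencoder",
    "VariationalAutoencoder",
    "AdversarialAutoencoder",
    "DeformableAutoencoder",
    "AppearanceDeformableAutoencoder",
    "build_network",
    "train",
]

_KINDS = ("ae", "vae", "aegan", "dae", "adae")


@dataclass
class NetworkSpec:
    """Configuration of one generative network."""

    kind: str
    spatial_dims: int = 2
    in_channels: int = 1
    out_channels: int | None = None
    encoder_channels: tuple[int, ...] = (20, 40, 80)
    latent_dim: int = 32
    appearance_latent_dim: int = 64
    data_kind: str = "label"  # "label" or "intensity"
    n_labels: int | None = None
    grid_shape: tuple[int, ...] | None = None
    loss_weights: dict = dc_field(
        default_factory=lambda: {
            "reconstruction": 1.0,
            "kl": 1.0,
            "adversarial": 1.0,
            "regularizer": 10.0,
        }
    )
    seed: int = 0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown network kind {self.kind!r}")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")


@dataclass
class TrainConfig:
    epochs: int = 150
    batch_size: int = 8
    learning_rate: float = 1e-3
    weight_decay: float = 1e-5
    seed: int = 0

    def __post_init__(self):
        if min(self.epochs, self.batch_size) < 1 or self.learning_rate <= 0:
            raise ValueError("training hyperparameters must be positive")


def _check_grid(grid_shape):
    if any(s % 8 for s in grid_shape):
        raise ValueError(
            f"grid {tuple(grid_shape)} must be divisible by 8 per spatial axis "
            "(three stride-2 convolutions)"
        )


class _Encoder(nn.Module):
    def __init__(self, dims, in_ch, channels, grid_shape, out_dim, rng,
                 variational=False):
        c1, c2, c3 = channels
        self.conv1 = nn.Conv(dims, in_ch, c1, stride=2, rng=rng)
        self.conv2 = nn.Conv(dims, c1, c2, stride=2, rng=rng)
        self.conv3 = nn.Conv(dims, c2, c3, stride=2, rng=rng)
        self.flat_dim = c3 * int(np.prod([s // 8 for s in grid_shape]))
        self.fc = nn.Linear(self.flat_dim, out_dim, rng=rng)
        self.variational = variational
        if variational:
            self.fc_logvar = nn.Linear(self.flat_dim, out_dim, rng=rng)

    def forward(self, x):
        h = self.conv1(x).relu()
        h = self.conv2(h).relu()
        h = self.conv3(h).relu()
        h = h.reshape((h.shape[0], self.flat_dim))
        if self.variational:
            return self.fc(h), self.fc_logvar(h)
        return self.fc(h)


class _Decoder(nn.Module):
    """Mirror of the encoder: fc, then 3x (upsample, conv)."""

    def __init__(self, dims, out_ch, channels, grid_shape, latent_dim, rng,
                 zero_last=False):
        c1, c2, c3 = channels
        self.grid8 = tuple(s // 8 for s in grid_shape)
        self.c3 = c3
        self.fc = nn.Linear(latent_dim, c3 * int(np.prod(self.grid8)), rng=rng)
        self.up = nn.Upsample()
        self.conv1 = nn.Conv(dims, c3, c2, rng=rng)
        self.conv2 = nn.Conv(dims, c2, c1, rng=rng)
        self.conv3 = nn.Conv(dims, c1, out_ch, rng=rng, zero_init=zero_last)

    def forward(self, z):
        h = self.fc(z).relu()
        h = h.reshape((z.shape[0], self.c3) + self.grid8)
        h = self.conv1(self.up(h)).relu()
        h = self.conv2(self.up(h)).relu()
        return self.conv3(self.up(h))


class _Discriminator(nn.Module):
    def __init__(self, dims, in_ch, channels, grid_shape, rng):
        self.enc = _Encoder(dims, in_ch, channels, grid_shape, 1, rng)

    def forward(self, x):
        return self.enc(x).sigmoid()


class ConvGenerativeModel(BaseEstimator):
    """Shared training/encoding machinery of the five network families.

    Subclasses set ``kind`` and override the decoding path. The estimator
    follows scikit-learn conventions: hyperparameters in ``__init__``,
    fitted state in trailing-underscore attributes, ``fit(X)`` where ``X``
    is an array of label images ``(N, *grid)`` (``data_kind="label"``) or
    intensity images (``data_kind="intensity"``).
    """

    kind = "ae"

    def __init__(
        self,
        latent_dim: int = 32,
        encoder_channels: tuple[int, ...] = (20, 40, 80),
        data_kind: str = "label",
        n_labels: int | None = None,
        epochs: int = 150,
        batch_size: int = 8,
        learning_rate: float = 1e-3,
        weight_decay: float = 1e-5,
        kl_weight: float = 1.0,
        adversarial_weight: float = 1.0,
        regularizer_weight: float = 10.0,
        random_state: int = 0,
    ):
        self.latent_dim = latent_dim
        self.encoder_channels = encoder_channels
        self.data_kind = data_kind
        self.n_labels = n_labels
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.kl_weight = kl_weight
        self.adversarial_weight = adversarial_weight
        self.regularizer_weight = regularizer_weight
        self.random_state = random_state

    # -- construction -----------------------------------------------------
    _variational = False

    @property
    def _total_latent(self) -> int:
        return self.latent_dim

    def _out_channels(self, in_ch: int) -> int:
        return in_ch

    def _build(self, grid_shape, in_ch, rng):
        _check_grid(grid_shape)
        dims = len(grid_shape)
        self.grid_shape_ = tuple(grid_shape)
        self.spatial_dims_ = dims
        self.in_channels_ = in_ch
        self.encoder_ = _Encoder(
            dims, in_ch, self.encoder_channels, grid_shape, self._total_latent,
            rng, variational=self._variational,
        )
        self.decoder_ = _Decoder(
            dims, self._out_channels(in_ch), self.encoder_channels, grid_shape,
            self._total_latent, rng,
        )

    # -- data plumbing -----------------------------------------------------
    def _to_channels(self, X: np.ndarray) -> np.ndarray:
        """(N, *grid) data -> (N, C, *grid) network input."""
        if self.data_kind == "label":
            return np.stack([label_to_onehot(x, self.n_labels_) for x in X])
        return np.asarray(X, dtype=float)[:, None]

    def _from_channels(self, out: np.ndarray):
        """(N, C, *grid) decoded output -> list of images."""
        if self.data_kind == "label":
            return [np.argmax(o, axis=0).astype(np.int64) for o in out]
        return [o[0] for o in out]

    # -- forward passes ----------------------------------------------------
    def _encode_tensor(self, x: Tensor):
        out = self.encoder_(x)
        if self._variational:
            return out  # (mu, logvar)
        return out, None

    def _decode_tensor(self, z: Tensor) -> Tensor:
        """Latent batch -> channel image batch (probabilities/intensities)."""
        raw = self.decoder_(z)
        if self.data_kind == "label":
            return raw.softmax(axis=1)
        return raw.sigmoid()

    def _reconstruction_loss(self, pred: Tensor, target: Tensor) -> Tensor:
        if self.data_kind == "label":
            return nn.generalized_dice_loss(pred, target)
        return nn.ssim_loss(pred, target)

    def _loss(self, batch: Tensor, rng) -> Tensor:
        mu, logvar = self._encode_tensor(batch)
        z = mu
        loss = Tensor(0.0)
        if self._variational:
            eps = Tensor(rng.standard_normal(mu.shape))
            z = mu + (logvar * 0.5).exp() * eps
            loss = loss + nn.kl_loss(mu, logvar) * self.kl_weight
        pred = self._decode_tensor(z)
        return loss + self._reconstruction_loss(pred, batch)

    # -- training ----------------------------------------------------------
    def _prepare_fit(self, X):
        X = np.asarray(X)
        if self.data_kind == "label":
            self.n_labels_ = (
                int(X.max()) if self.n_labels is None else self.n_labels
            )
        else:
            self.n_labels_ = None
        rng = np.random.default_rng(self.random_state)
        self._build(X.shape[1:], self._to_channels(X[:1]).shape[1], rng)
        return X, rng

    def _optimizers(self):
        return [
            nn.Adam(
                self.encoder_.parameters() + self.decoder_.parameters(),
                lr=self.learning_rate, weight_decay=self.weight_decay,
            )
        ]

    def _train_step(self, batch: Tensor, optimizers, rng) -> float:
        (opt,) = optimizers
        loss = self._loss(batch, rng)
        opt.zero_grad()
        loss.backward()
        opt.step()
        return loss.item()

    def fit(self, X, y=None):
        X, rng = self._prepare_fit(X)
        if len(X) == 0:
            raise ValueError("empty training set")
        data = self._to_channels(X)
        optimizers = self._optimizers()
        n = len(data)
        self.loss_history_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                batch = Tensor(data[idx])
                step_loss = self._train_step(batch, optimizers, rng)
                if not np.isfinite(step_loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}; lower the learning rate"
                    )
                epoch_losses.append(step_loss)
            self.loss_history_.append(float(np.mean(epoch_losses)))
        Z = self._encode_array(data)
        self.latent_mean_ = Z.mean(axis=0)
        self.latent_sd_ = Z.std(axis=0)
        self.is_fitted_ = True
        return self

    # -- generative contract ----------------------------------------------
    def _encode_array(self, data: np.ndarray, chunk: int = 16) -> np.ndarray:
        outs = []
        for start in range(0, len(data), chunk):
            mu, _ = self._encode_tensor(Tensor(data[start : start + chunk]))
            outs.append(mu.data)
        return np.concatenate(outs, axis=0)

    def encode(self, x) -> np.ndarray:
        """Image(s) -> latent vector(s) (the posterior mean when variational)."""
        if not hasattr(self, "encoder_"):
            raise RuntimeError("network is not built; call fit first")
        x = np.asarray(x)
        single = x.ndim == self.spatial_dims_
        batch = x[None] if single else x
        Z = self._encode_array(self._to_channels(batch))
        return Z[0] if single else Z

    def decode(self, z):
        if not hasattr(self, "decoder_"):
            raise RuntimeError("network is not built; call fit first")
        z = np.asarray(z, dtype=float)
        single = z.ndim == 1
        zb = z[None] if single else z
        out = self._decode_tensor(Tensor(zb)).data
        imgs = self._from_channels(out)
        return imgs[0] if single else np.stack(imgs)

    def reconstruct(self, x):
        if not getattr(self, "is_fitted_", False):
            raise RuntimeError("model is not trained")
        return self.decode(self.encode(x))

    def sample(self, n: int, random_state=None, latent_stats=None) -> np.ndarray:
        """Decode ``z ~ Normal(latent mean, latent sd)`` per dimension."""
        if not getattr(self, "is_fitted_", False):
            raise RuntimeError("model is not trained")
        if latent_stats is None:
            mean, sd = self.latent_mean_, self.latent_sd_
        else:
            mean, sd = (np.asarray(a, dtype=float) for a in latent_stats)
        rng = np.random.default_rng(random_state)
        Z = rng.normal(mean, sd, size=(n, self._total_latent))
        return self.decode(Z)

    @property
    def n_parameters_(self) -> int:
        total = self.encoder_.n_parameters() + self.decoder_.n_parameters()
        if hasattr(self, "discriminator_"):
            total += self.discriminator_.n_parameters()
        return total


class Autoencoder(ConvGenerativeModel):
    """Plain autoencoder: reconstruction loss only."""

    kind = "ae"


class VariationalAutoencoder(ConvGenerativeModel):
    """VAE: reparameterized latent with a KL pull toward N(0, 1)."""

    kind = "vae"
    _variational = True


class AdversarialAutoencoder(ConvGenerativeModel):
    """Autoencoder with an adversarial discriminator (AE-GAN).

    The reconstruction loss is combined with the non-saturating GAN
    generator loss on reconstructed images; a separately parameterized
    discriminator (same convolutional shape as the encoder, ending in a
    real/fake probability) is updated in an alternating step.
    """

    kind = "aegan"

    def _build(self, grid_shape, in_ch, rng):
        super()._build(grid_shape, in_ch, rng)
        self.discriminator_ = _Discriminator(
            len(grid_shape), in_ch, self.encoder_channels, grid_shape, rng
        )

    def _optimizers(self):
        return super()._optimizers() + [
            nn.Adam(
                self.discriminator_.parameters(),
                lr=self.learning_rate, weight_decay=self.weight_decay,
            )
        ]

    def _train_step(self, batch, optimizers, rng):
        opt_ae, opt_d = optimizers
        mu, _ = self._encode_tensor(batch)
        pred = self._decode_tensor(mu)
        gen_term, _ = nn.adversarial_losses(
            self.discriminator_(batch), self.discriminator_(pred)
        )
        loss = self._reconstruction_loss(pred, batch) + gen_term * self.adversarial_weight
        opt_ae.zero_grad()
        self.discriminator_.zero_grads()
        loss.backward()
        opt_ae.step()
        # discriminator step on detached reconstructions
        fake = Tensor(pred.data)
        _, disc_term = nn.adversarial_losses(
            self.discriminator_(batch.detach()), self.discriminator_(fake)
        )
        opt_d.zero_grad()
        disc_term.backward()
        opt_d.step()
        return loss.item()


def _zero_grads(module: nn.Module):
    for p in module.parameters():
        p.grad = None


nn.Module.zero_grads = _zero_grads


class DeformableAutoencoder(ConvGenerativeModel):
    """Template-deformation autoencoder (DAE).

    The decoder emits a displacement field that backward-warps a fixed
    template built from the training set (voxelwise majority label for
    shapes, mean image for intensities), so every decoded image is a
    deformed copy of the template: structures present in the template can
    never vanish from a decoding. Trained with the reconstruction loss plus
    the weighted diffusion+L1 field regularizer and a KL latent constraint.
    """

    kind = "dae"
    _variational = True

    def _build(self, grid_shape, in_ch, rng):
        _check_grid(grid_shape)
        dims = len(grid_shape)
        self.grid_shape_ = tuple(grid_shape)
        self.spatial_dims_ = dims
        self.in_channels_ = in_ch
        self.encoder_ = _Encoder(
            dims, in_ch, self.encoder_channels, grid_shape, self._total_latent,
            rng, variational=True,
        )
        self.decoder_ = _Decoder(
            dims, dims, self.encoder_channels, grid_shape, self.latent_dim,
            rng, zero_last=True,
        )

    def _make_template(self, data: np.ndarray) -> np.ndarray:
        """(N, C, *grid) training stack -> (1, C, *grid) fixed template.

        Labels: voxelwise majority vote. Small structures can lose every
        majority vote under shape variation, which would make them
        unrepresentable by any deformation of the template; in that case
        the medoid training image (closest to the voxelwise mean) is used
        instead, which by construction contains every structure it shows.
        """
        mean = data.mean(axis=0)
        if self.data_kind == "label":
            lab = np.argmax(mean, axis=0)
            seen = {c for c in range(data.shape[1]) if data[:, c].any()}
            if not seen.issubset(set(np.unique(lab))):
                dists = ((data - mean[None]) ** 2).sum(axis=tuple(range(1, data.ndim)))
                order = np.argsort(dists)
                counts = [
                    sum(1 for c in seen if data[i, c].any()) for i in order
                ]
                best = order[int(np.argmax(counts))]
                return data[best][None].astype(float)
            mean = label_to_onehot(lab.astype(np.int64), data.shape[1] - 1)
        return mean[None]

    def _prepare_fit(self, X):
        X, rng = super()._prepare_fit(X)
        self.template_ = self._make_template(self._to_channels(np.asarray(X)))
        return X, rng

    def decode_field(self, z) -> np.ndarray:
        """Latent vector(s) -> displacement field(s), without warping."""
        z = np.asarray(z, dtype=float)
        single = z.ndim == 1
        zb = z[None] if single else z
        phi = self.decoder_(Tensor(zb)).data
        return phi[0] if single else phi

    def _shape_latent(self, z: Tensor) -> Tensor:
        return z

    def _decode_tensor(self, z: Tensor) -> Tensor:
        phi = self.decoder_(self._shape_latent(z))
        self._last_phi = phi
        return warp_channels(Tensor(self.template_), phi)

    def _loss(self, batch, rng):
        mu, logvar = self._encode_tensor(batch)
        eps = Tensor(rng.standard_normal(mu.shape))
        z = mu + (logvar * 0.5).exp() * eps
        pred = self._decode_tensor(z)
        loss = self._reconstruction_loss(pred, batch)
        loss = loss + nn.kl_loss(mu, logvar) * self.kl_weight
        reg = nn.displacement_regularizer(
            self._last_phi, weight=self.regularizer_weight
        )
        return loss + reg


class AppearanceDeformableAutoencoder(DeformableAutoencoder):
    """ADAE: deformation plus a decoded per-image intensity offset.

    The latent splits into ``[z_s, z_a]``; one decoder turns ``z_s`` into a
    displacement field, a second turns ``z_a`` into an intensity offset
    added to the template before warping: ``x ~ (t + a) o phi``. Intensity
    data only.
    """

    kind = "adae"

    def __init__(
        self,
        latent_dim: int = 32,
        appearance_latent_dim: int = 64,
        encoder_channels: tuple[int, ...] = (20, 40, 80),
        data_kind: str = "intensity",
        n_labels: int | None = None,
        epochs: int = 150,
        batch_size: int = 8,
        learning_rate: float = 1e-3,
        weight_decay: float = 1e-5,
        kl_weight: float = 1.0,
        adversarial_weight: float = 1.0,
        regularizer_weight: float = 10.0,
        random_state: int = 0,
    ):
        super().__init__(
            latent_dim=latent_dim,
            encoder_channels=encoder_channels,
            data_kind=data_kind,
            n_labels=n_labels,
            epochs=epochs,
            batch_size=batch_size,
            learning_rate=learning_rate,
            weight_decay=weight_decay,
            kl_weight=kl_weight,
            adversarial_weight=adversarial_weight,
            regularizer_weight=regularizer_weight,
            random_state=random_state,
        )
        self.appearance_latent_dim = appearance_latent_dim

    @property
    def _total_latent(self) -> int:
        return self.latent_dim + self.appearance_latent_dim

    def _build(self, grid_shape, in_ch, rng):
        if self.data_kind != "intensity":
            raise ValueError("the appearance DAE models intensity images")
        super()._build(grid_shape, in_ch, rng)
        self.appearance_decoder_ = _Decoder(
            len(grid_shape), in_ch, self.encoder_channels, grid_shape,
            self.appearance_latent_dim, rng, zero_last=True,
        )

    def _optimizers(self):
        return [
            nn.Adam(
                self.encoder_.parameters()
                + self.decoder_.parameters()
                + self.appearance_decoder_.parameters(),
                lr=self.learning_rate, weight_decay=self.weight_decay,
            )
        ]

    def _decode_tensor(self, z: Tensor) -> Tensor:
        z_s = z[:, : self.latent_dim]
        z_a = z[:, self.latent_dim :]
        phi = self.decoder_(z_s)
        offset = self.appearance_decoder_(z_a)
        self._last_phi = phi
        return warp_channels(Tensor(self.template_) + offset, phi)

    @property
    def n_components_(self):
        return (self.latent_dim, self.appearance_latent_dim)


_KIND_TO_CLASS = {
    "ae": Autoencoder,
    "vae": VariationalAutoencoder,
    "aegan": AdversarialAutoencoder,
    "dae": DeformableAutoencoder,
    "adae": AppearanceDeformableAutoencoder,
}


def build_network(spec: NetworkSpec, config: TrainConfig | None = None):
    """Instantiate the estimator for a :class:`NetworkSpec`.

    If ``spec.grid_shape`` is given, the layers are materialized
    immediately (so ``encode`` works before training); otherwise they are
    built from the data when ``fit`` is first called.
    """
    cls = _KIND_TO_CLASS[spec.kind]
    config = config or TrainConfig(seed=spec.seed)
    kwargs = dict(
        latent_dim=spec.latent_dim,
        encoder_channels=tuple(spec.encoder_channels),
        data_kind=spec.data_kind,
        n_labels=spec.n_labels,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        weight_decay=config.weight_decay,
        kl_weight=spec.loss_weights.get("kl", 1.0),
        adversarial_weight=spec.loss_weights.get("adversarial", 1.0),
        regularizer_weight=spec.loss_weights.get("regularizer", 10.0),
        random_state=spec.seed,
    )
    if spec.kind == "adae":
        kwargs["appearance_latent_dim"] = spec.appearance_latent_dim
    model = cls(**kwargs)
    if spec.grid_shape is not None:
        rng = np.random.default_rng(spec.seed)
        if spec.data_kind == "label":
            if spec.n_labels is None:
                raise ValueError("n_labels is required to pre-build a label network")
            model.n_labels_ = spec.n_labels
            in_ch = spec.n_labels + 1
        else:
            model.n_labels_ = None
            in_ch = spec.in_channels
        model._build(tuple(spec.grid_shape), in_ch, rng)
        if spec.kind in ("dae", "adae"):
            # template filled in by fit; pre-building only wires the layers
            model.template_ = None
    return model


def train(model: ConvGenerativeModel, population, config: TrainConfig | None = None,
          subset: str = "train"):
    """Fit a network on a synthetic population's training split."""
    if config is not None:
        model.set_params(
            epochs=config.epochs, batch_size=config.batch_size,
            learning_rate=config.learning_rate, weight_decay=config.weight_decay,
            random_state=config.seed,
        )
    if model.data_kind == "label":
        X = population.labels(subset)
    else:
        X = population.appearances(subset)
    if len(X) == 0:
        raise ValueError("training split is empty")
    model.fit(X)
    return model, model.loss_history_
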