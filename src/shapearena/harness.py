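"""Experiment orchestration: training-size sweeps, interpolation, reports.

Each model family is wrapped in a small adapter that presents the shared
generative contract at the image level (label or intensity images), so one
sweep loop can train and evaluate statistical and neural models
identically. Folds follow the multi-fold rule: four folds for training
sizes below 100, two folds otherwise, with per-(size, fold) seeded
subsampling of the training split; results are averaged over folds and
written incrementally so an interrupted sweep resumes where it stopped.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from functools import partial
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import (
    MetricReport,
    compactness,
    generalization_ability,
    latent_ambiguity_score,
    likeness_dsi,
    normality_fraction,
)
from .neural import (
    AdversarialAutoencoder,
    AppearanceDeformableAutoencoder,
    Autoencoder,
    DeformableAutoencoder,
    VariationalAutoencoder,
)
from .representation import assd, l1_distance, landmarks_to_label, missing_structures
from .statistical import (
    LocalityShapeModel,
    StatisticalAppearanceModel,
    StatisticalShapeModel,
)
from .synthetic import (
    Instance,
    Population,
    build_deformation_basis,
    build_template,
    sample_population,
)

__all__ = [
    "SweepConfig",
    "InterpolationResult",
    "LandmarkModelAdapter",
    "ImageModelAdapter",
    "AppearanceModelAdapter",
    "make_model",
    "make_population",
    "fold_count",
    "run_sweep",
    "interpolation_experiment",
    "render_report",
]

log = logging.getLogger("shapearena")

STATISTICAL_MODELS = ("ssm", "lssm", "sam", "lsam")
NEURAL_MODELS = ("ae", "vae", "aegan", "dae", "adae")


# ---------------------------------------------------------------------------
# adapters


class LandmarkModelAdapter:
    """Expose a landmark-space PCA model as a label-image generator.

    ``encode`` operates on the instance's landmarks (the model's native
    representation); decoded and sampled shapes are rasterized to label
    images, with landmarks clipped into the grid so extreme samples stay
    rasterizable.
    """

    def __init__(self, model, grid_shape, layout):
        self.model = model
        self.grid_shape = tuple(grid_shape)
        self.layout = layout

    def fit(self, instances: list[Instance]):
        X = np.stack([inst.landmarks for inst in instances])
        self.model.fit(X)
        return self

    def _rasterize(self, shape_vec: np.ndarray) -> np.ndarray:
        pts = shape_vec.reshape(-1, self.layout.ndim)
        upper = np.asarray(self.grid_shape, dtype=float) - 1.0
        pts = np.clip(pts, 0.0, upper)
        return landmarks_to_label(pts.ravel(), self.grid_shape, self.layout)

    @staticmethod
    def _landmarks(item) -> np.ndarray:
        return item.landmarks if isinstance(item, Instance) else np.asarray(item)

    def encode(self, item) -> np.ndarray:
        return self.model.encode(self._landmarks(item))

    def decode(self, z) -> np.ndarray:
        return self._rasterize(self.model.decode(z))

    def reconstruct(self, item) -> np.ndarray:
        return self._rasterize(self.model.reconstruct(self._landmarks(item)))

    def reencode(self, z) -> np.ndarray:
        # encode-decode round trip in the model's native landmark space
        return self.model.encode(self.model.decode(z))

    def sample(self, n: int, random_state=None) -> list[np.ndarray]:
        shapes = self.model.sample(n, random_state=random_state)
        return [self._rasterize(s) for s in shapes]

    @property
    def n_components_(self):
        return self.model.n_components_


class ImageModelAdapter:
    """Uniform wrapper for networks operating directly on images."""

    def __init__(self, model, data_kind: str = "label"):
        self.model = model
        self.data_kind = data_kind

    def _image(self, item):
        if isinstance(item, Instance):
            return item.label if self.data_kind == "label" else item.appearance
        return np.asarray(item)

    def fit(self, instances):
        X = np.stack([self._image(i) for i in instances])
        self.model.fit(X)
        return self

    def encode(self, item):
        return self.model.encode(self._image(item))

    def decode(self, z):
        return self.model.decode(z)

    def reconstruct(self, item):
        return self.model.reconstruct(self._image(item))

    def sample(self, n, random_state=None):
        return list(self.model.sample(n, random_state=random_state))

    @property
    def n_components_(self):
        if hasattr(self.model, "n_components_"):
            return self.model.n_components_
        return self.model.latent_dim


class AppearanceModelAdapter:
    """Wrap the statistical appearance model; items are instances."""

    def __init__(self, model: StatisticalAppearanceModel):
        self.model = model

    @staticmethod
    def _pair(item):
        return (item.landmarks, item.appearance)

    def fit(self, instances):
        X = np.stack([i.landmarks for i in instances])
        A = np.stack([i.appearance for i in instances])
        self.model.fit(X, A)
        return self

    def encode(self, item):
        return self.model.encode(self._pair(item))

    def decode(self, z):
        return self.model.decode(z)[1]

    def reconstruct(self, item):
        return self.model.reconstruct(self._pair(item))[1]

    def sample(self, n, random_state=None):
        return [a for _, a in self.model.sample(n, random_state=random_state)]

    @property
    def n_components_(self):
        return self.model.n_components_


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SweepConfig:
    """One sweep: a population, a model list, training sizes, metrics."""

    kind: str = "thorax-like"
    grid_shape: tuple[int, ...] = (64, 64)
    n_population: int = 120
    n_modes: int = 8
    offset_scale: float = 0.05
    models: tuple[str, ...] = ("ssm", "lssm", "ae", "vae", "dae")
    sizes: tuple[int, ...] = (5, 10, 20, 40)
    data_kind: str = "label"  # which representation networks consume
    metrics: tuple[str, ...] = ("ga", "spec", "dsi", "las", "norm", "compact", "missing")
    distance: str = "assd"
    latent_dim: int = 32
    encoder_channels: tuple[int, ...] = (20, 40, 80)
    epochs: int = 50
    batch_size: int = 8
    learning_rate: float = 1e-3
    n_eval: int = 12
    out_dir: str | None = None
    seed: int = 0
    schema: int = 1

    def __post_init__(self):
        sizes = tuple(int(s) for s in self.sizes)
        if any(s <= 0 for s in sizes) or any(
            b <= a for a, b in zip(sizes, sizes[1:])
        ):
            raise ValueError("sizes must be positive and increasing")
        self.sizes = sizes


@dataclass
class InterpolationResult:
    endpoints: tuple
    steps: int
    decodings: list
    profile_to_first: np.ndarray
    profile_to_last: np.ndarray


# ---------------------------------------------------------------------------
# model / population factories


def make_population(config: SweepConfig) -> Population:
    template = build_template(config.kind, config.grid_shape, seed=config.seed)
    basis = build_deformation_basis(template, config.n_modes, seed=config.seed + 1)
    return sample_population(
        template,
        basis,
        config.n_population,
        offset_scale=config.offset_scale,
        seed=config.seed + 2,
    )


def make_model(name: str, population: Population, config: SweepConfig, seed: int = 0):
    template = population.template
    ndim = template.layout.ndim
    net_kwargs = dict(
        latent_dim=config.latent_dim,
        encoder_channels=tuple(config.encoder_channels),
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        data_kind=config.data_kind,
        random_state=seed,
    )
    if name == "ssm":
        return LandmarkModelAdapter(
            StatisticalShapeModel(), template.grid_shape, template.layout
        )
    if name == "lssm":
        return LandmarkModelAdapter(
            LocalityShapeModel(ndim=ndim), template.grid_shape, template.layout
        )
    if name in ("sam", "lsam"):
        return AppearanceModelAdapter(
            StatisticalAppearanceModel(ndim=ndim, locality=name == "lsam")
        )
    cls = {
        "ae": Autoencoder,
        "vae": VariationalAutoencoder,
        "aegan": AdversarialAutoencoder,
        "dae": DeformableAutoencoder,
    }.get(name)
    if cls is not None:
        return ImageModelAdapter(cls(**net_kwargs), data_kind=config.data_kind)
    if name == "adae":
        net_kwargs["data_kind"] = "intensity"
        return ImageModelAdapter(
            AppearanceDeformableAutoencoder(**net_kwargs), data_kind="intensity"
        )
    raise ValueError(f"unknown model {name!r}")


def fold_count(train_size: int) -> int:
    """Multi-fold rule: four folds below 100 training samples, two above."""
    return 4 if train_size < 100 else 2


def _distance_for(config: SweepConfig, template):
    if config.distance == "assd":
        return partial(assd, structures=template.structures)
    return l1_distance


def _eval_image(item, config: SweepConfig):
    if config.data_kind == "label":
        return item.label
    return item.appearance


# ---------------------------------------------------------------------------
# the sweep


def _evaluate_cell(
    adapter, name, size, fold, test_items, config, template, seed,
    train_items=None,
) -> MetricReport:
    """Evaluate one trained model.

    Generalization ability, LAS and latent normality use the held-out test
    items; specificity and likeness compare generated samples against the
    fold's real training images (specificity asks whether samples resemble
    the training data), with the sample count matching the reference count.
    """
    dist = _distance_for(config, template)
    as_image = partial(_eval_image, config=config)
    rep = MetricReport(model=name, train_size=size, fold=fold)
    wanted = set(config.metrics)
    if "ga" in wanted:
        rep.ga = generalization_ability(adapter, test_items, dist, as_image)
    refs = train_items if train_items is not None else test_items
    samples = None
    if wanted & {"spec", "dsi", "missing"}:
        samples = adapter.sample(max(len(refs), 2), random_state=seed)
    if "spec" in wanted:
        real_imgs = [as_image(r) for r in refs]
        rep.specificity = float(
            np.mean([min(dist(r, s) for r in real_imgs) for s in samples])
        )
    if "dsi" in wanted:
        rep.likeness = likeness_dsi(
            [as_image(r) for r in refs], samples, dist, seed=seed
        )
    if "las" in wanted:
        rep.las = latent_ambiguity_score(adapter, test_items)
    if "norm" in wanted:
        Z = np.stack([adapter.encode(r) for r in test_items])
        if len(Z) >= 8 and Z.shape[1] > 0:
            rep.normality_pct = normality_fraction(Z)
    if "compact" in wanted:
        rep.compactness = compactness(adapter)
    if "missing" in wanted and config.data_kind == "label":
        expected = template.structures
        rep.missing_pct = 100.0 * float(
            np.mean([missing_structures(s, expected) for s in samples])
        )
    return rep


def run_sweep(config: SweepConfig, population: Population | None = None) -> list[MetricReport]:
    """Train and evaluate every (model, size, fold) cell of a sweep.

    Completed cells found in the output CSV are not recomputed; a failing
    cell is recorded as failed and the sweep continues.
    """
    population = population or make_population(config)
    train_idx = population.split["train"]
    if max(config.sizes) > len(train_idx):
        raise ValueError("largest size exceeds the training split")
    test_items = [population.instances[i] for i in population.split["test"]]
    test_items = test_items[: config.n_eval]
    template = population.template

    out_csv = None
    done: set[tuple] = set()
    reports: list[MetricReport] = []
    if config.out_dir is not None:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out_csv = out_dir / "metrics.csv"
        if out_csv.exists():
            prev = pd.read_csv(out_csv)
            for _, row in prev.iterrows():
                done.add((row["model"], int(row["train_size"]), int(row["fold"])))
                reports.append(MetricReport(**{
                    k: row[k] for k in row.index if k in MetricReport.__dataclass_fields__
                }))

    for name in config.models:
        for size in config.sizes:
            for fold in range(fold_count(size)):
                key = (name, size, fold)
                if key in done:
                    log.info("skip completed cell %s", key)
                    continue
                seed = int(
                    np.random.SeedSequence(
                        [config.seed, config.sizes.index(size), fold]
                    ).generate_state(1)[0] % (2**31)
                )
                rng = np.random.default_rng(seed)
                subset = rng.choice(len(train_idx), size=size, replace=False)
                instances = [population.instances[train_idx[i]] for i in subset]
                t0 = time.time()
                try:
                    adapter = make_model(name, population, config, seed=seed)
                    adapter.fit(instances)
                    rep = _evaluate_cell(
                        adapter, name, size, fold, test_items, config, template,
                        seed, train_items=instances,
                    )
                except Exception as exc:  # noqa: BLE001 - cell isolation
                    log.warning("cell %s failed: %s", key, exc)
                    rep = MetricReport(model=name, train_size=size, fold=fold,
                                       failed=True)
                log.info("cell %s done in %.1fs", key, time.time() - t0)
                reports.append(rep)
                if out_csv is not None:
                    pd.DataFrame([r.to_dict() for r in reports]).to_csv(
                        out_csv, index=False
                    )
    return reports


# ---------------------------------------------------------------------------
# interpolation


def interpolation_experiment(model, a, b, steps: int = 20, dist=None,
                             as_image=None):
    """Decode the linear path between the latent codes of two images.

    ``z_t = (1 - t) f(a) + t f(b)`` on ``steps`` equally spaced ``t`` in
    [0, 1]; for each decoding the distance to both endpoints is recorded.
    """
    if steps < 2:
        raise ValueError("steps must be >= 2")
    if dist is None:
        dist = l1_distance
    image_of = as_image or (lambda x: x)
    za = np.asarray(model.encode(a), dtype=float)
    zb = np.asarray(model.encode(b), dtype=float)
    ts = np.linspace(0.0, 1.0, steps)
    decodings = [model.decode((1 - t) * za + t * zb) for t in ts]
    img_a, img_b = image_of(a), image_of(b)
    prof_a = np.array([dist(img_a, d) for d in decodings])
    prof_b = np.array([dist(img_b, d) for d in decodings])
    return InterpolationResult(
        endpoints=(a, b), steps=steps, decodings=decodings,
        profile_to_first=prof_a, profile_to_last=prof_b,
    )


# ---------------------------------------------------------------------------
# reporting


def render_report(reports: list[MetricReport], out_dir) -> list[Path]:
    """Write per-cell CSV, fold-averaged summary JSON and per-metric plots."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not reports:
        raise ValueError("no reports to render")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame([r.to_dict() for r in reports])
    files = []
    csv_path = out_dir / "metrics.csv"
    df.to_csv(csv_path, index=False)
    files.append(csv_path)

    numeric = ["ga", "specificity", "likeness", "las", "normality_pct", "missing_pct"]
    ok = df[~df["failed"].astype(bool)]
    summary = (
        ok.groupby(["model", "train_size"])[numeric]
        .mean()
        .round(6)
        .reset_index()
        .to_dict(orient="records")
    )
    json_path = out_dir / "summary.json"
    json_path.write_text(json.dumps(summary, indent=2, default=float))
    files.append(json_path)

    for metric in numeric:
        if ok[metric].isna().all():
            continue
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for model, grp in ok.groupby("model"):
            agg = grp.groupby("train_size")[metric].mean()
            if metric == "missing_pct":
                ax.bar(
                    [f"{model}\nN={n}" for n in agg.index], agg.values, label=model
                )
            else:
                ax.plot(agg.index, agg.values, marker="o", label=model)
        ax.set_xlabel("training size N" if metric != "missing_pct" else "")
        ax.set_ylabel(metric)
        ax.legend(fontsize=7)
        fig.tight_layout()
        path = out_dir / f"{metric}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        files.append(path)
    return files
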