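"""Reading and writing populations and fitted models.

Populations are directories: 2D labels and appearances as PNG (labels one
integer per pixel, appearances 16-bit), 3D volumes as NIfTI, landmarks as
CSV tables with columns ``structure, point_index, x, y[, z]`` and run
metadata (seed, modes, amplitudes, splits, layout) as JSON. Models are an
``.npz`` of arrays plus a JSON sidecar describing their configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .neural import _KIND_TO_CLASS, ConvGenerativeModel
from .representation import LandmarkLayout
from .statistical import LocalityShapeModel, LocalitySchedule, StatisticalShapeModel
from .synthetic import DeformationBasis, Instance, Population, Template

__all__ = [
    "write_population",
    "read_population",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# images


def _write_image(path: Path, arr: np.ndarray, kind: str):
    if arr.ndim == 2:
        if kind == "label":
            iio.imwrite(path.with_suffix(".png"), arr.T.astype(np.uint8))
        else:
            data = np.clip(arr, 0.0, 1.0)
            iio.imwrite(
                path.with_suffix(".png"), (data.T * 65535).round().astype(np.uint16)
            )
    else:
        dtype = np.int16 if kind == "label" else np.float32
        img = nib.Nifti1Image(arr.astype(dtype), affine=np.eye(4))
        nib.save(img, str(path.with_suffix(".nii.gz")))


def _read_image(path: Path, kind: str) -> np.ndarray:
    if path.suffix == ".png":
        arr = np.asarray(iio.imread(path)).T
        if kind == "label":
            return arr.astype(np.int64)
        return arr.astype(float) / 65535.0
    arr = np.asanyarray(nib.load(str(path)).dataobj)
    if kind == "label":
        return arr.astype(np.int64)
    return arr.astype(float)


def _landmark_frame(landmarks: np.ndarray, layout: LandmarkLayout) -> pd.DataFrame:
    rows = []
    per = layout.split(landmarks)
    cols = ["x", "y", "z"][: layout.ndim]
    for lab in layout.structures:
        for i, pt in enumerate(per[lab]):
            rows.append({"structure": lab, "point_index": i,
                         **dict(zip(cols, pt))})
    return pd.DataFrame(rows)


def _layout_to_dict(layout: LandmarkLayout) -> dict:
    return {
        "ndim": layout.ndim,
        "structures": list(layout.structures),
        "points_per_structure": list(layout.points_per_structure),
        "sphere_grid": list(layout.sphere_grid) if layout.sphere_grid else None,
    }


def _layout_from_dict(d: dict) -> LandmarkLayout:
    return LandmarkLayout(
        ndim=d["ndim"],
        structures=tuple(d["structures"]),
        points_per_structure=tuple(d["points_per_structure"]),
        sphere_grid=tuple(d["sphere_grid"]) if d.get("sphere_grid") else None,
    )


# ---------------------------------------------------------------------------
# populations


def write_population(pop: Population, out_dir) -> Path:
    out = Path(out_dir)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    (out / "appearances").mkdir(exist_ok=True)
    (out / "landmarks").mkdir(exist_ok=True)

    tpl = pop.template
    _write_image(out / "template_label", tpl.label_image, "label")
    _write_image(out / "template_appearance", tpl.appearance_image, "intensity")
    _landmark_frame(tpl.landmarks, tpl.layout).to_csv(
        out / "template_landmarks.csv", index=False
    )
    np.savez_compressed(
        out / "basis.npz", modes=pop.basis.modes, amplitudes=pop.basis.amplitudes
    )
    for i, inst in enumerate(pop.instances):
        _write_image(out / "labels" / f"{i:04d}", inst.label, "label")
        _write_image(out / "appearances" / f"{i:04d}", inst.appearance, "intensity")
        _landmark_frame(inst.landmarks, tpl.layout).to_csv(
            out / "landmarks" / f"{i:04d}.csv", index=False
        )
    meta = {
        "schema": 1,
        "kind": tpl.kind,
        "grid_shape": list(tpl.grid_shape),
        "seed": pop.seed,
        "template_seed": tpl.seed,
        "k": pop.basis.k,
        "amplitudes": pop.basis.amplitudes.tolist(),
        "smoothness": pop.basis.smoothness,
        "basis_seed": pop.basis.seed,
        "split": pop.split,
        "layout": _layout_to_dict(tpl.layout),
        "true_coefficients": [
            inst.true_coefficients.tolist() for inst in pop.instances
        ],
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2))
    return out


def _read_landmarks(path: Path, layout: LandmarkLayout) -> np.ndarray:
    df = pd.read_csv(path)
    cols = ["x", "y", "z"][: layout.ndim]
    per = {}
    for lab in layout.structures:
        sub = df[df["structure"] == lab].sort_values("point_index")
        per[lab] = sub[cols].to_numpy(dtype=float)
    return layout.join(per)


def read_population(in_dir) -> Population:
    src = Path(in_dir)
    meta = json.loads((src / "metadata.json").read_text())
    layout = _layout_from_dict(meta["layout"])
    grid_shape = tuple(meta["grid_shape"])
    ext = ".png" if layout.ndim == 2 else ".nii.gz"

    template = Template(
        kind=meta["kind"],
        grid_shape=grid_shape,
        layout=layout,
        landmarks=_read_landmarks(src / "template_landmarks.csv", layout),
        label_image=_read_image(src / f"template_label{ext}", "label"),
        appearance_image=_read_image(src / f"template_appearance{ext}", "intensity"),
        seed=meta["template_seed"],
    )
    with np.load(src / "basis.npz") as npz:
        basis = DeformationBasis(
            modes=npz["modes"],
            amplitudes=npz["amplitudes"],
            smoothness=meta["smoothness"],
            seed=meta["basis_seed"],
        )
    instances = []
    coeffs = meta["true_coefficients"]
    n = len(coeffs)
    for i in range(n):
        instances.append(
            Instance(
                landmarks=_read_landmarks(src / "landmarks" / f"{i:04d}.csv", layout),
                label=_read_image(src / "labels" / f"{i:04d}{ext}", "label"),
                appearance=_read_image(
                    src / "appearances" / f"{i:04d}{ext}", "intensity"
                ),
                true_coefficients=np.asarray(coeffs[i], dtype=float),
                true_intensity_offset=np.zeros(grid_shape),
            )
        )
    return Population(
        instances=instances,
        template=template,
        basis=basis,
        split={k: list(v) for k, v in meta["split"].items()},
        seed=meta["seed"],
    )


# ---------------------------------------------------------------------------
# models


def save_model(model, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    if isinstance(model, StatisticalShapeModel):
        meta = {
            "family": "lssm" if isinstance(model, LocalityShapeModel) else "ssm",
            "params": {"variability_threshold": model.variability_threshold},
        }
        if isinstance(model, LocalityShapeModel):
            meta["params"]["ndim"] = model.ndim
            meta["levels"] = [float(r) for r in model.schedule_.levels]
        arrays = {
            "mean": model.mean_,
            "components": model.components_,
            "mode_variances": model.mode_variances_,
            "latent_mean": model.latent_mean_,
            "latent_sd": model.latent_sd_,
        }
    elif isinstance(model, ConvGenerativeModel):
        meta = {
            "family": model.kind,
            "params": model.get_params(),
            "grid_shape": list(model.grid_shape_),
            "n_labels": model.n_labels_,
            "in_channels": model.in_channels_,
        }
        parts = [("encoder", model.encoder_), ("decoder", model.decoder_)]
        if hasattr(model, "appearance_decoder_"):
            parts.append(("adecoder", model.appearance_decoder_))
        if hasattr(model, "discriminator_"):
            parts.append(("disc", model.discriminator_))
        for tag, module in parts:
            for i, a in enumerate(module.state_arrays()):
                arrays[f"{tag}_{i}"] = a
        meta["parts"] = [tag for tag, _ in parts]
        if getattr(model, "template_", None) is not None:
            arrays["template"] = model.template_
        arrays["latent_mean"] = model.latent_mean_
        arrays["latent_sd"] = model.latent_sd_
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path.with_suffix(".npz")


def load_model(path):
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    npz = np.load(path.with_suffix(".npz"))
    family = meta["family"]
    if family in ("ssm", "lssm"):
        if family == "lssm":
            model = LocalityShapeModel(**meta["params"])
            model.schedule_ = LocalitySchedule(levels=tuple(meta["levels"]))
        else:
            model = StatisticalShapeModel(**meta["params"])
        model.mean_ = npz["mean"]
        model.components_ = npz["components"]
        model.mode_variances_ = npz["mode_variances"]
        model.latent_mean_ = npz["latent_mean"]
        model.latent_sd_ = npz["latent_sd"]
        model.n_components_ = model.components_.shape[0]
        model.n_features_in_ = model.mean_.shape[0]
        return model
    cls = _KIND_TO_CLASS[family]
    model = cls(**meta["params"])
    rng = np.random.default_rng(0)
    model.n_labels_ = meta["n_labels"]
    model._build(tuple(meta["grid_shape"]), meta["in_channels"], rng)
    modules = {"encoder": model.encoder_, "decoder": model.decoder_}
    if "adecoder" in meta["parts"]:
        modules["adecoder"] = model.appearance_decoder_
    if "disc" in meta["parts"]:
        modules["disc"] = model.discriminator_
    for tag, module in modules.items():
        arrays = []
        i = 0
        while f"{tag}_{i}" in npz:
            arrays.append(npz[f"{tag}_{i}"])
            i += 1
        module.load_state_arrays(arrays)
    if "template" in npz:
        model.template_ = npz["template"]
    model.latent_mean_ = npz["latent_mean"]
    model.latent_sd_ = npz["latent_sd"]
    model.is_fitted_ = True
    return model
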