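"""End-to-end hierarchy: preprocess → retina → V1 → TICA → spiking readout.

A labelled dataset is a directory tree ``<root>/<class_name>/<images>``.
Training runs every image through masking, illumination normalization,
the ON/OFF retina stage and the Gabor bank; the orientation maps are
max-pooled, TICA is fit on vectorized patches sampled from the pooled
maps of the *training* images only, and each image's patch-grid TICA
energies (concatenated over patch locations and orientation maps) form
the analog feature vector that is rank-order encoded for the spiking
output layer.  One neuronal map per class is trained with the batch
average rule and thresholds are calibrated from the training waves.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.measure import block_reduce

from .config import PipelineConfig
from .errors import DataError, FormatError, InputError
from .gabor import filter_bank, v1_response
from .preproc import (
    GrayImage,
    RetinaKernelParams,
    apply_face_mask,
    load_gray_image,
    normalize_illumination,
    retina_response,
)
from .spiking import (
    InhibitionProfile,
    NeuronalMap,
    classify,
    encode_rank_order,
    set_thresholds,
    train_map,
)
from . import tica as tica_mod
from .tica import TicaModel, NeighborhoodMatrix, WhiteningModel, fit_tica

logger = logging.getLogger(__name__)

FORMAT_VERSION = "1"

__all__ = [
    "TrainedPipeline",
    "discover_dataset",
    "extract_feature_vector",
    "run_train",
    "run_predict",
    "run_evaluate",
]


def _stage(stage: str, path, exc: Exception) -> Exception:
    return type(exc)(f"[stage {stage}] {path}: {exc}")


def discover_dataset(root) -> list[tuple[str, str]]:
    """Return sorted (path, class) pairs from ``<root>/<class>/<image>``."""
    root = Path(root)
    if not root.is_dir():
        raise DataError(f"dataset root {root} is not a directory")
    items: list[tuple[str, str]] = []
    for cls_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for f in sorted(cls_dir.iterdir()):
            if f.suffix.lower() in (".png", ".pgm", ".jpg", ".jpeg"):
                items.append((str(f), cls_dir.name))
    if not items:
        raise DataError(f"no images found under {root}")
    return items


def _preprocess(img: GrayImage, cfg: PipelineConfig) -> GrayImage:
    out = apply_face_mask(img, cfg.mask_margin)
    if cfg.illum_normalize:
        out = normalize_illumination(out, cfg.illum_method)
    return out


def _pooled_maps(img: GrayImage, cfg: PipelineConfig, bank) -> np.ndarray:
    """Stack of pooled V1 modulus maps, shape (n_scales*8, h, w)."""
    pre = _preprocess(img, cfg)
    if cfg.v1_input == "on_plus_off":
        acc = np.zeros_like(pre.pixels)
        for sigma in cfg.retina_sigmas:
            maps = retina_response(
                pre, RetinaKernelParams(sigma=sigma, gain=cfg.retina_gain)
            )
            acc += maps.on_map + maps.off_map
        v1_in = acc / len(cfg.retina_sigmas)
    else:
        v1_in = pre.pixels
    om = v1_response(v1_in, bank)
    n_s, n_o, h, w = om.maps.shape
    flat = om.maps.reshape(n_s * n_o, h, w)
    if cfg.pool_block > 1:
        flat = block_reduce(flat, (1, cfg.pool_block, cfg.pool_block), np.max)
    return flat


def _patch_grid(maps_stack: np.ndarray, patch: int) -> np.ndarray:
    """Non-overlapping patch vectors from every map, row-major order."""
    n_maps, h, w = maps_stack.shape
    ny, nx = h // patch, w // patch
    if ny == 0 or nx == 0:
        raise DataError(f"pooled maps {h}x{w} smaller than patch {patch}")
    cropped = maps_stack[:, : ny * patch, : nx * patch]
    blocks = cropped.reshape(n_maps, ny, patch, nx, patch)
    blocks = blocks.transpose(0, 1, 3, 2, 4).reshape(n_maps * ny * nx, patch * patch)
    return blocks


def extract_feature_vector(
    maps_stack: np.ndarray, model: TicaModel, patch: int
) -> np.ndarray:
    """Concatenated TICA neighborhood energies of the patch grid."""
    patches = _patch_grid(maps_stack, patch)
    _, G = tica_mod.transform(model, patches)
    return G.ravel()


@dataclass
class TrainedPipeline:
    """Serialized outcome of a training run."""

    config: PipelineConfig
    classes: list[str]
    tica: TicaModel
    maps: list[NeuronalMap]
    format_version: str = FORMAT_VERSION

    @property
    def profile(self) -> InhibitionProfile:
        return InhibitionProfile(
            amplitude=self.config.inhib_amplitude,
            radius_sigma=self.config.inhib_radius,
        )

    def save(self, path) -> None:
        weights = np.stack([m.shared_weights for m in self.maps])
        thresholds = np.array([m.threshold for m in self.maps])
        n_trained = np.array([m.n_trained for m in self.maps])
        np.savez_compressed(
            path,
            format_version=np.array(self.format_version),
            config_json=np.array(json.dumps(self.config.to_dict())),
            classes=np.array(self.classes),
            tica_W=self.tica.W,
            tica_H=self.tica.H.h,
            tica_H_width=np.array(self.tica.H.width),
            tica_H_topology=np.array(self.tica.H.topology),
            tica_V=self.tica.whitening.V,
            tica_mean=self.tica.whitening.mean_vec,
            tica_A=self.tica.A,
            tica_seed=np.array(self.tica.seed),
            tica_trace=np.array(self.tica.likelihood_trace),
            map_weights=weights,
            map_thresholds=thresholds,
            map_n_trained=n_trained,
        )

    @classmethod
    def load(cls, path) -> "TrainedPipeline":
        try:
            with np.load(path, allow_pickle=False) as z:
                version = str(z["format_version"])
                if version != FORMAT_VERSION:
                    raise FormatError(
                        f"unknown model format version {version!r}"
                    )
                cfg = PipelineConfig.from_dict(json.loads(str(z["config_json"])))
                classes = [str(c) for c in z["classes"]]
                H = NeighborhoodMatrix(
                    h=z["tica_H"],
                    width=int(z["tica_H_width"]),
                    topology=str(z["tica_H_topology"]),
                )
                whitening = WhiteningModel(
                    V=z["tica_V"],
                    mean_vec=z["tica_mean"],
                    n_keep=z["tica_V"].shape[0],
                )
                tica = TicaModel(
                    W=z["tica_W"],
                    H=H,
                    whitening=whitening,
                    A=z["tica_A"],
                    alpha=cfg.tica_alpha,
                    beta=cfg.tica_beta,
                    seed=int(z["tica_seed"]),
                    likelihood_trace=list(z["tica_trace"]),
                )
                maps = [
                    NeuronalMap(
                        class_label=classes[i],
                        shared_weights=z["map_weights"][i],
                        mod=cfg.mod,
                        threshold=float(z["map_thresholds"][i]),
                        n_trained=int(z["map_n_trained"][i]),
                    )
                    for i in range(len(classes))
                ]
        except FormatError:
            raise
        except Exception as exc:
            raise FormatError(f"corrupt model archive {path}: {exc}") from exc
        return cls(config=cfg, classes=classes, tica=tica, maps=maps)


def _train_items(
    items: list[tuple[str, str]], cfg: PipelineConfig
) -> tuple[TrainedPipeline, dict]:
    classes = sorted({c for _, c in items})
    counts = {c: sum(1 for _, cc in items if cc == c) for c in classes}
    if len(classes) < 2:
        raise DataError("training needs at least 2 classes")
    if any(n < 2 for n in counts.values()):
        raise DataError(f"every class needs >= 2 images, got {counts}")
    bank = filter_bank(
        cfg.gabor_n_scales, cfg.gabor_sigma, cfg.gabor_kmax, cfg.gabor_spacing
    )
    pooled: dict[str, np.ndarray] = {}
    for path, _ in items:
        try:
            img = load_gray_image(path)
            pooled[path] = _pooled_maps(img, cfg, bank)
        except Exception as exc:
            raise _stage("feature-extraction", path, exc) from exc
        logger.debug("pooled maps %s: %s", path, pooled[path].shape)

    all_patches = np.concatenate(
        [_patch_grid(pooled[p], cfg.patch_size) for p, _ in items]
    )
    rng = np.random.default_rng(cfg.seed)
    n_take = min(cfg.n_patches, all_patches.shape[0])
    sel = rng.choice(all_patches.shape[0], size=n_take, replace=False)
    tica_seed = int(rng.integers(0, 2**31 - 1))
    model = fit_tica(
        all_patches[sel],
        cfg.tica_components,
        m=cfg.tica_m,
        topology=cfg.tica_topology,
        alpha=cfg.tica_alpha,
        beta=cfg.tica_beta,
        learn_rate=cfg.tica_learn_rate,
        n_iter=cfg.tica_n_iter,
        tol=cfg.tica_tol,
        seed=tica_seed,
    )

    waves_by_class: dict[str, list] = {c: [] for c in classes}
    for path, cls in items:
        feats = extract_feature_vector(pooled[path], model, cfg.patch_size)
        waves_by_class[cls].append(encode_rank_order(feats, cfg.keep_frac))
    n_inputs = waves_by_class[classes[0]][0].n_inputs
    maps = []
    for cls in classes:
        blank = NeuronalMap(
            class_label=cls, shared_weights=np.zeros(n_inputs), mod=cfg.mod
        )
        maps.append(train_map(blank, waves_by_class[cls], cfg.mod))
    maps = set_thresholds(maps, waves_by_class, cfg.threshold_margin)

    mean_psp = {
        m.class_label: float(
            np.mean([m.psp(w) for w in waves_by_class[m.class_label]])
        )
        for m in maps
    }
    report = {
        "class_counts": counts,
        "likelihood_trace": list(model.likelihood_trace),
        "mean_own_class_psp": mean_psp,
        "thresholds": {m.class_label: float(m.threshold) for m in maps},
        "config": cfg.to_dict(),
    }
    return TrainedPipeline(config=cfg, classes=classes, tica=model, maps=maps), report


def run_train(dataset_root, cfg: PipelineConfig) -> tuple[TrainedPipeline, dict]:
    """Train the full hierarchy on a labelled directory tree."""
    return _train_items(discover_dataset(dataset_root), cfg)


def run_predict(model: TrainedPipeline, inputs: list[str]) -> pd.DataFrame:
    """Predict labels for a list of image paths.

    One row per input: path, predicted label and the per-class raw /
    post-inhibition PSPs.  Unreadable images yield a row marked
    ``error`` and the run continues.
    """
    cfg = model.config
    bank = filter_bank(
        cfg.gabor_n_scales, cfg.gabor_sigma, cfg.gabor_kmax, cfg.gabor_spacing
    )
    cols_raw = [f"raw_{c}" for c in model.classes]
    cols_post = [f"post_{c}" for c in model.classes]
    rows = []
    for path in inputs:
        row: dict = {"image_path": str(path)}
        try:
            img = load_gray_image(path)
            stack = _pooled_maps(img, cfg, bank)
            feats = extract_feature_vector(stack, model.tica, cfg.patch_size)
            label, scores = classify(
                feats, model.maps, cfg.keep_frac, model.profile
            )
            row["predicted_label"] = label
            for c in model.classes:
                row[f"raw_{c}"] = scores[c]["raw"]
                row[f"post_{c}"] = scores[c]["post"]
        except (InputError, OSError) as exc:
            logger.warning("prediction failed for %s: %s", path, exc)
            row["predicted_label"] = "error"
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["image_path", "predicted_label", *cols_raw, *cols_post]
    )


def _stratified_split(
    items: list[tuple[str, str]], frac: float, seed: int
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in sorted({c for _, c in items}):
        members = [it for it in items if it[1] == cls]
        if len(members) < 2:
            raise DataError(f"class {cls!r} has fewer than 2 images")
        perm = rng.permutation(len(members))
        n_train = max(1, int(round(frac * len(members))))
        n_train = min(n_train, len(members) - 1)
        train += [members[i] for i in perm[:n_train]]
        test += [members[i] for i in perm[n_train:]]
    return train, test


def run_evaluate(
    dataset_root,
    cfg: PipelineConfig,
    split_seed: int = 0,
    permute_seed: int | None = None,
) -> dict:
    """Stratified split, train on the training part, score the held-out part.

    ``permute_seed`` shuffles the *training* labels (a chance-level
    control: accuracy should then sit near 1/n_classes).
    """
    items = discover_dataset(dataset_root)
    train, test = _stratified_split(items, cfg.split_frac, split_seed)
    if permute_seed is not None:
        rng = np.random.default_rng(permute_seed)
        labels = [c for _, c in train]
        perm = rng.permutation(len(labels))
        train = [(p, labels[perm[i]]) for i, (p, _) in enumerate(train)]
    model, train_report = _train_items(train, cfg)
    preds = run_predict(model, [p for p, _ in test])
    truth = [c for _, c in test]
    pred = list(preds["predicted_label"])
    correct = sum(int(p == t) for p, t in zip(pred, truth))
    accuracy = correct / len(truth)
    recall = {}
    for cls in model.classes:
        idx = [i for i, t in enumerate(truth) if t == cls]
        recall[cls] = (
            sum(int(pred[i] == cls) for i in idx) / len(idx) if idx else float("nan")
        )
    confusion = pd.crosstab(
        pd.Series(truth, name="true"), pd.Series(pred, name="predicted")
    )
    return {
        "accuracy": accuracy,
        "n_train": len(train),
        "n_test": len(test),
        "per_class_recall": recall,
        "confusion": confusion,
        "train_report": train_report,
        "predictions": preds,
    }
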