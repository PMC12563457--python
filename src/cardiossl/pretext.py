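"""Pretext-task construction and the associated objectives.

Four pretexts are supported:

* ``noise`` — originals (pseudo-label 0) vs. copies perturbed with additive
  zero-mean Gaussian noise of standard deviation ``noise_factor`` (label 1);
  a binary discrimination task trained with BCE.
* ``rotation`` — originals (label 0) vs. copies rotated by a lossless 90 or
  180 degree re-indexing (label 1), also binary BCE.
* ``reconstruction`` — the input is its own target; trained with MSE by an
  encoder-decoder.
* ``contrastive`` — two stochastically augmented views per image (flip,
  crop-and-resize, brightness, contrast), trained with the NT-Xent loss on
  L2-normalized embeddings.

The binary pretexts are exactly balanced by construction and every sample
carries provenance back to its source image, which the training harness
uses to keep an original and its transformed sibling in the same fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

__all__ = [
    "PretextDataset",
    "LossSpec",
    "AugmentConfig",
    "make_noise_pretext",
    "make_rotation_pretext",
    "make_reconstruction_pretext",
    "make_simclr_views",
    "bce_loss",
    "mse_loss",
    "nt_xent_loss",
    "nt_xent_loss_and_grad",
    "pretext_objective",
]

TASK_KINDS = ("noise", "rotation", "reconstruction", "contrastive")


@dataclass(frozen=True)
class LossSpec:
    """Objective selector: BCE for pseudo-labeled tasks, MSE for
    reconstruction, NT-Xent (temperature ``temperature``) for contrastive."""

    kind: str = "bce"
    temperature: float = 0.5
    probability_clip: float = 1e-7

    def __post_init__(self):
        if self.kind not in ("bce", "mse", "nt_xent"):
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if not 0 < self.probability_clip < 0.5:
            raise ValueError("probability_clip must be in (0, 0.5)")


_COMPATIBLE = {"noise": "bce", "rotation": "bce",
               "reconstruction": "mse", "contrastive": "nt_xent"}


@dataclass
class PretextDataset:
    """Images plus pretext supervision.

    Exactly one of ``labels`` (binary tasks), ``targets`` (reconstruction)
    or ``views2`` (contrastive second views) is set, matching ``task_kind``.
    """

    inputs: np.ndarray
    task_kind: str
    labels: np.ndarray | None = None
    targets: np.ndarray | None = None
    views2: np.ndarray | None = None
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if self.task_kind not in TASK_KINDS:
            raise ValueError(f"unknown task_kind {self.task_kind!r}")
        if self.task_kind in ("noise", "rotation"):
            if self.labels is None or len(self.labels) != len(self.inputs):
                raise ValueError("binary pretext needs one label per input")
            if int(self.labels.sum()) * 2 != len(self.inputs):
                raise ValueError("binary pretext must be exactly balanced")
        if self.task_kind == "reconstruction" and self.targets is None:
            raise ValueError("reconstruction pretext needs targets")
        if self.task_kind == "contrastive" and (
                self.views2 is None or len(self.views2) != len(self.inputs)):
            raise ValueError("contrastive pretext needs aligned second views")

    def __len__(self) -> int:
        return len(self.inputs)


def make_noise_pretext(images: np.ndarray, noise_factor: float = 0.01,
                       seed: int = 0,
                       ids: list[str] | None = None) -> PretextDataset:
    """Original-vs-noisy discrimination set (2N samples from N originals)."""
    images = np.asarray(images, dtype=np.float32)
    if noise_factor < 0:
        raise ValueError("noise_factor must be >= 0")
    if noise_factor == 0:
        warnings.warn("noise_factor = 0: both pretext classes are identical",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    noisy = np.clip(
        images + rng.normal(0.0, noise_factor, images.shape), 0.0, 1.0
    ).astype(np.float32)
    n = len(images)
    ids = list(ids) if ids is not None else [str(i) for i in range(n)]
    prov = pd.DataFrame({
        "source_id": ids + ids,
        "transform": ["identity"] * n + [f"gaussian_noise({noise_factor})"] * n,
    })
    return PretextDataset(np.concatenate([images, noisy]), "noise",
                          labels=np.r_[np.zeros(n), np.ones(n)].astype(np.int64),
                          provenance=prov)


def rotate_image(image: np.ndarray, angle: int) -> np.ndarray:
    """Exact array re-indexing rotation (counter-clockwise, degrees)."""
    if angle % 90 != 0:
        raise ValueError("only multiples of 90 degrees are lossless")
    k = (angle // 90) % 4
    if k % 2 == 1 and image.shape[0] != image.shape[1]:
        raise ValueError("90-degree rotation requires square images")
    return np.rot90(image, k=k, axes=(0, 1))


def make_rotation_pretext(images: np.ndarray, angles: tuple[int, ...] = (90, 180),
                          seed: int = 0,
                          ids: list[str] | None = None) -> PretextDataset:
    """Original-vs-rotated discrimination set; angles drawn uniformly."""
    images = np.asarray(images, dtype=np.float32)
    if images.shape[1] != images.shape[2] and any(a % 180 for a in angles):
        raise ValueError("90-degree rotations need square images")
    rng = np.random.default_rng(seed)
    drawn = rng.choice(np.asarray(angles), size=len(images))
    rotated = np.stack([rotate_image(img, int(a))
                        for img, a in zip(images, drawn)])
    n = len(images)
    ids = list(ids) if ids is not None else [str(i) for i in range(n)]
    prov = pd.DataFrame({
        "source_id": ids + ids,
        "transform": ["identity"] * n + [f"rot{int(a)}" for a in drawn],
    })
    return PretextDataset(np.concatenate([images, rotated]), "rotation",
                          labels=np.r_[np.zeros(n), np.ones(n)].astype(np.int64),
                          provenance=prov)


def make_reconstruction_pretext(images: np.ndarray,
                                ids: list[str] | None = None) -> PretextDataset:
    """Identity-target reconstruction set (no pseudo-labels, no doubling)."""
    images = np.asarray(images, dtype=np.float32)
    ids = list(ids) if ids is not None else [str(i) for i in range(len(images))]
    prov = pd.DataFrame({"source_id": ids,
                         "transform": ["identity"] * len(images)})
    return PretextDataset(images, "reconstruction", targets=images,
                          provenance=prov)


@dataclass(frozen=True)
class AugmentConfig:
    """Stochastic view augmentations for the contrastive pretext."""

    flip_p: float = 0.5
    crop_area: tuple[float, float] = (0.6, 1.0)
    brightness: float = 0.2
    contrast: tuple[float, float] = (0.8, 1.2)

    @classmethod
    def identity(cls) -> "AugmentConfig":
        return cls(flip_p=0.0, crop_area=(1.0, 1.0), brightness=0.0,
                   contrast=(1.0, 1.0))


def _augment(img: np.ndarray, cfg: AugmentConfig,
             rng: np.random.Generator) -> np.ndarray:
    out = img
    if rng.random() < cfg.flip_p:
        out = out[:, ::-1]
    if rng.random() < cfg.flip_p:
        out = out[::-1, :]
    area = rng.uniform(*cfg.crop_area)
    size = img.shape[0]
    side = max(1, int(round(size * np.sqrt(area))))
    if side < size:
        top = rng.integers(0, size - side + 1)
        left = rng.integers(0, size - side + 1)
        crop = out[top:top + side, left:left + side]
        out = _sk_resize(crop, (size, size), order=1, mode="edge",
                         anti_aliasing=False, preserve_range=True)
    scale = rng.uniform(*cfg.contrast)
    shift = rng.uniform(-cfg.brightness, cfg.brightness)
    out = (out - 0.5) * scale + 0.5 + shift
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def make_simclr_views(images: np.ndarray, aug_cfg: AugmentConfig | None = None,
                      seed: int = 0,
                      ids: list[str] | None = None) -> PretextDataset:
    """Two independently augmented views per image, aligned index-wise."""
    images = np.asarray(images, dtype=np.float32)
    cfg = aug_cfg or AugmentConfig()
    rng = np.random.default_rng(seed)
    v1 = np.stack([_augment(img, cfg, rng) for img in images]) if len(images) \
        else images
    v2 = np.stack([_augment(img, cfg, rng) for img in images]) if len(images) \
        else images
    ids = list(ids) if ids is not None else [str(i) for i in range(len(images))]
    prov = pd.DataFrame({"source_id": ids,
                         "transform": ["simclr_views"] * len(images)})
    return PretextDataset(v1, "contrastive", views2=v2, provenance=prov)


def write_pretext_dir(dataset: PretextDataset, path) -> "pd.DataFrame":
    """Serialize a pretext dataset to PNGs plus a CSV manifest.

    The manifest carries ``id,path,pseudo_label,task_kind,source_id``;
    reconstruction/contrastive datasets write an empty pseudo-label.
    Second views (contrastive) are written alongside with a ``_v2`` suffix.
    """
    import os

    from PIL import Image

    root = os.fspath(path)
    os.makedirs(root, exist_ok=True)
    rows = []
    for i, img in enumerate(dataset.inputs):
        rel = f"{dataset.task_kind}_{i:05d}.png"
        arr = np.round(np.asarray(img) * 255.0).astype(np.uint8)
        Image.fromarray(arr, mode="RGB").save(os.path.join(root, rel),
                                              format="PNG", compress_level=6)
        if dataset.views2 is not None:
            arr2 = np.round(np.asarray(dataset.views2[i]) * 255.0
                            ).astype(np.uint8)
            Image.fromarray(arr2, mode="RGB").save(
                os.path.join(root, rel.replace(".png", "_v2.png")),
                format="PNG", compress_level=6)
        rows.append({
            "id": f"{dataset.task_kind}_{i:05d}",
            "path": rel,
            "pseudo_label": (int(dataset.labels[i])
                             if dataset.labels is not None else ""),
            "task_kind": dataset.task_kind,
            "source_id": dataset.provenance["source_id"].iloc[i]
            if len(dataset.provenance) else "",
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(root, "manifest.csv"), index=False)
    return manifest


def bce_loss(y, y_hat, probability_clip: float = 1e-7) -> float:
    """Binary cross-entropy, mean over the batch."""
    y = np.asarray(y, dtype=np.float64)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    p = np.clip(np.asarray(y_hat, dtype=np.float64),
                probability_clip, 1.0 - probability_clip)
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


def mse_loss(x, x_hat) -> float:
    """Mean squared error over all elements."""
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {x_hat.shape}")
    return float(np.mean((x - x_hat) ** 2))


def _nt_xent_logits(z: np.ndarray, temperature: float):
    z = np.asarray(z, dtype=np.float64)
    n2 = len(z)
    if n2 < 4 or n2 % 2 != 0:
        raise ValueError("need 2N embeddings with N >= 2")
    norms = np.linalg.norm(z, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-5):
        raise ValueError("embeddings must be L2-normalized")
    sim = z @ z.T / temperature
    np.fill_diagonal(sim, -np.inf)  # exclude self-similarity
    partner = np.arange(n2) ^ 1     # pairs are (0,1), (2,3), ...
    return sim, partner


def nt_xent_loss(z: np.ndarray, temperature: float = 0.5) -> float:
    """NT-Xent over 2N aligned, unit-norm embeddings (pairs adjacent).

    Mean over all 2N anchors of ``-log softmax(sim/t)[partner]`` where the
    softmax runs over the 2N-1 non-self similarities.
    """
    sim, partner = _nt_xent_logits(z, temperature)
    m = sim.max(axis=1, keepdims=True)
    logsumexp = m[:, 0] + np.log(np.exp(sim - m).sum(axis=1))
    pos = sim[np.arange(len(z)), partner]
    return float(np.mean(logsumexp - pos))


def nt_xent_loss_and_grad(z: np.ndarray, temperature: float = 0.5):
    """Loss plus its gradient with respect to the (normalized) embeddings."""
    sim, partner = _nt_xent_logits(z, temperature)
    n2 = len(z)
    m = sim.max(axis=1, keepdims=True)
    e = np.exp(sim - m)
    p = e / e.sum(axis=1, keepdims=True)
    loss = float(np.mean(-np.log(p[np.arange(n2), partner])))
    a = p.copy()
    a[np.arange(n2), partner] -= 1.0
    a /= n2
    grad = (a + a.T) @ np.asarray(z, dtype=np.float64) / temperature
    return loss, grad


def pretext_objective(dataset: PretextDataset, model, loss: LossSpec) -> float:
    """Mean per-sample objective of ``model`` on a pretext dataset.

    ``model`` must expose ``predict(x)`` returning probabilities for binary
    tasks, reconstructions for the generative task, or unit-norm embeddings
    for the contrastive task.
    """
    if _COMPATIBLE[dataset.task_kind] != loss.kind:
        raise ValueError(
            f"loss {loss.kind!r} incompatible with task {dataset.task_kind!r}")
    if loss.kind == "bce":
        return bce_loss(dataset.labels, model.predict(dataset.inputs),
                        probability_clip=loss.probability_clip)
    if loss.kind == "mse":
        return mse_loss(dataset.targets, model.predict(dataset.inputs))
    z1 = model.predict(dataset.inputs)
    z2 = model.predict(dataset.views2)
    z = np.empty((2 * len(z1), z1.shape[1]), dtype=np.float64)
    z[0::2], z[1::2] = z1, z2
    return nt_xent_loss(z, temperature=loss.temperature)
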