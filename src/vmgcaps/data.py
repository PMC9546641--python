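"""Seeded synthetic inputs: Gaussian-cluster point sets, capsule vote
fixtures, and a procedural shape-image dataset emulating a small, imbalanced
grayscale medical-imaging task (with an out-of-distribution class held out),
plus an IDX reader/writer so synthetic and real MNIST-format files go
through the same loader.

Every generator is a pure function of its arguments including the seed.
Images carry additive Gaussian pixel noise clipped to [0, 1] -- digital
acquisition noise is part of the emulated conditions and nothing here
denoises it.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.draw import disk as _draw_disk, polygon as _draw_polygon

from .routing import VoteTensor
from .vbgmm import InvalidInputError

__all__ = ["ShapesDataset", "ShapesBundle", "gen_gmm_data",
           "gen_vote_fixture", "gen_shapes_dataset", "read_idx", "write_idx",
           "save_bundle_idx", "load_bundle_idx"]

SHAPE_NAMES = ("disk", "square", "triangle", "cross")


# ---------------------------------------------------------------------------
# Gaussian mixture point sets
# ---------------------------------------------------------------------------

def gen_gmm_data(K: int, D: int, N: int, separation: float = 8.0,
                 weights: np.ndarray | None = None, seed: int = 0,
                 ) -> tuple[np.ndarray, np.ndarray, dict]:
    """K unit-covariance Gaussian clusters with means pairwise at least
    ``separation`` apart.

    Returns (points, labels, params) where params holds the generative
    means/weights and the realized per-cluster sample means and counts.
    """
    if separation < 0:
        raise InvalidInputError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    if weights is None:
        weights = np.full(K, 1.0 / K)
    weights = np.asarray(weights, dtype=float)
    if K == 1:
        means = np.zeros((1, D))
    elif K <= D + 1:
        # regular simplex with edge = separation, randomly rotated and
        # centered at the origin: every pair of means is exactly
        # `separation` apart and the constellation stays compact, so the
        # weakly informative prior (mu0 = data mean) barely shrinks the
        # recovered means
        M = np.eye(K) - 1.0 / K                  # centered simplex, edge √2
        U, S, _ = np.linalg.svd(M)
        coords = U[:, :K - 1] * S[:K - 1]        # (K, K-1), distances kept
        emb = np.zeros((K, D))
        emb[:, :K - 1] = coords * (separation / np.sqrt(2.0))
        Q = np.linalg.qr(rng.standard_normal((D, D)))[0]
        means = emb @ Q.T
    else:
        scale = max(1.0, separation)
        means = None
        for _ in range(200):
            cand = rng.normal(0.0, scale, size=(K, D))
            d = np.linalg.norm(cand[:, None] - cand[None, :], axis=-1)
            if d[np.triu_indices(K, 1)].min() >= separation:
                means = cand - cand.mean(axis=0)
                break
        if means is None:
            raise InvalidInputError("could not place means pairwise >= "
                                    f"separation apart (K={K}, D={D})")
    labels = rng.choice(K, size=N, p=weights)
    points = means[labels] + rng.standard_normal((N, D))
    counts = np.bincount(labels, minlength=K)
    sample_means = np.full((K, D), np.nan)
    for k in range(K):
        if counts[k]:
            sample_means[k] = points[labels == k].mean(axis=0)
    params = {"means": means, "weights": weights, "cov": np.eye(D),
              "counts": counts, "sample_means": sample_means}
    return points, labels, params


def gen_vote_fixture(n_lower: int, K: int, n_clusters: int = 1,
                     noise_sd: float = 0.1, seed: int = 0, D: int = 16,
                     ) -> VoteTensor:
    """Lower-capsule votes around ``n_clusters`` centers in R^D; all lower
    activations are 1.

    Votes are expressed relative to each higher capsule's reference pose,
    as a trained transform layer emits them: capsule k's reference equals
    cluster k's center (extra capsules beyond ``n_clusters`` get random
    references), so votes from lower capsules that belong to cluster k
    agree near zero in capsule k's frame. Absolute votes identical across
    capsule frames would make the routing components exactly
    interchangeable -- a symmetric fixed point.
    """
    if n_clusters > K:
        raise InvalidInputError("n_clusters must not exceed K")
    rng = np.random.default_rng(seed)
    centers = rng.normal(0.0, 1.0, size=(n_clusters, D))
    refs = np.vstack([centers, rng.normal(0.0, 1.0, size=(K - n_clusters, D))])
    assign = np.arange(n_lower) % n_clusters
    base = centers[assign] + noise_sd * rng.standard_normal((n_lower, D))
    votes = base[:, None, :] - refs[None, :, :]
    return VoteTensor(votes=votes, lower_activations=np.ones(n_lower))


# ---------------------------------------------------------------------------
# procedural shapes
# ---------------------------------------------------------------------------

def _render_shape(name: str, size: int, center: np.ndarray, radius: float,
                  angle: float) -> np.ndarray:
    img = np.zeros((size, size))
    if name == "disk":
        rr, cc = _draw_disk(center, radius, shape=img.shape)
        img[rr, cc] = 1.0
        return img
    if name == "square":
        angles = angle + np.deg2rad([45, 135, 225, 315])
    elif name == "triangle":
        angles = angle + np.deg2rad([90, 210, 330])
    elif name == "cross":
        # union of two bars, each a thin rectangle through the center
        for a in (angle, angle + np.pi / 2):
            u = np.array([np.cos(a), np.sin(a)])
            v = np.array([-np.sin(a), np.cos(a)])
            half_w = 0.3 * radius
            corners = np.array([center + radius * u + half_w * v,
                                center + radius * u - half_w * v,
                                center - radius * u - half_w * v,
                                center - radius * u + half_w * v])
            rr, cc = _draw_polygon(corners[:, 0], corners[:, 1],
                                   shape=img.shape)
            img[rr, cc] = 1.0
        return img
    else:
        raise InvalidInputError(f"unknown shape {name!r}")
    pts = center[None, :] + radius * np.stack(
        [np.sin(angles), np.cos(angles)], axis=1)
    rr, cc = _draw_polygon(pts[:, 0], pts[:, 1], shape=img.shape)
    img[rr, cc] = 1.0
    return img


@dataclass
class ShapesDataset:
    """One split of the procedural shape-image set."""

    images: np.ndarray            # (M, size, size, 1) in [0, 1]
    labels: np.ndarray            # (M,) class indices
    class_names: tuple[str, ...]
    split: str = "train"

    @property
    def imbalance(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=len(self.class_names))


@dataclass
class ShapesBundle:
    train: ShapesDataset
    val: ShapesDataset
    test: ShapesDataset
    ood: ShapesDataset | None = None
    meta: dict = field(default_factory=dict)


def _make_split(shapes, counts, size, noise_sd, rng, split) -> ShapesDataset:
    images, labels = [], []
    margin = size // 2 - size // 8
    for cls, (name, count) in enumerate(zip(shapes, counts)):
        for _ in range(count):
            center = size / 2 + rng.uniform(-size / 5, size / 5, size=2)
            radius = rng.uniform(size / 6.5, size / 3.6)
            angle = rng.uniform(0, 2 * np.pi)
            img = _render_shape(name, size, center, radius, angle)
            img = np.clip(img + noise_sd * rng.standard_normal(img.shape),
                          0.0, 1.0)
            images.append(img)
            labels.append(cls)
    images = np.asarray(images)[..., None]
    labels = np.asarray(labels, dtype=np.int64)
    order = rng.permutation(len(labels))
    return ShapesDataset(images=images[order], labels=labels[order],
                         class_names=tuple(shapes), split=split)


def gen_shapes_dataset(n_classes: int = 3,
                       counts: tuple[int, ...] = (60, 40, 20),
                       size: int = 32, noise_sd: float = 0.05, seed: int = 0,
                       ood_class: str | None = "cross",
                       val_frac: float = 0.34, test_frac: float = 0.34,
                       n_ood: int = 30) -> ShapesBundle:
    """Imbalanced shape-image dataset with train/val/test splits and an
    optional out-of-distribution split drawn from a held-out shape class.

    ``counts`` are the exact per-class training counts (imbalanced by
    default, echoing the small skewed medical-image setting this stands in
    for); validation and test use ``val_frac``/``test_frac`` of them,
    rounded up. The OOD class never appears in train/val/test.
    """
    if n_classes < 2:
        raise InvalidInputError("need at least two classes")
    if len(counts) != n_classes or any(c < 1 for c in counts):
        raise InvalidInputError("counts must list a positive int per class")
    in_dist = [s for s in SHAPE_NAMES if s != ood_class][:n_classes]
    if len(in_dist) < n_classes:
        raise InvalidInputError("not enough distinct shape classes")
    rng = np.random.default_rng(seed)
    val_counts = [max(1, int(np.ceil(c * val_frac))) for c in counts]
    test_counts = [max(1, int(np.ceil(c * test_frac))) for c in counts]
    train = _make_split(in_dist, counts, size, noise_sd, rng, "train")
    val = _make_split(in_dist, val_counts, size, noise_sd, rng, "val")
    test = _make_split(in_dist, test_counts, size, noise_sd, rng, "test")
    ood = None
    if ood_class is not None:
        ood = _make_split([ood_class], [n_ood], size, noise_sd, rng, "ood")
    meta = {"n_classes": n_classes, "counts": list(counts), "size": size,
            "noise_sd": noise_sd, "seed": seed, "ood_class": ood_class}
    return ShapesBundle(train=train, val=val, test=test, ood=ood, meta=meta)


# ---------------------------------------------------------------------------
# IDX file format (MNIST-style)
# ---------------------------------------------------------------------------

_IDX_IMAGES_MAGIC = 0x00000803
_IDX_LABELS_MAGIC = 0x00000801


def read_idx(path: str | Path) -> np.ndarray:
    """Parse an IDX file: big-endian magic, dimension sizes, raw bytes.
    Image files (magic 0x00000803) come back scaled to [0, 1]; label files
    (0x00000801) come back as integer arrays."""
    raw = Path(path).read_bytes()
    magic = struct.unpack(">I", raw[:4])[0]
    if magic == _IDX_IMAGES_MAGIC:
        ndim = 3
    elif magic == _IDX_LABELS_MAGIC:
        ndim = 1
    else:
        raise InvalidInputError(f"unrecognized IDX magic 0x{magic:08x}")
    dims = struct.unpack(f">{ndim}I", raw[4:4 + 4 * ndim])
    data = np.frombuffer(raw[4 + 4 * ndim:], dtype=np.uint8).reshape(dims)
    if magic == _IDX_IMAGES_MAGIC:
        return data.astype(np.float64) / 255.0
    return data.astype(np.int64)


def write_idx(path: str | Path, array: np.ndarray) -> None:
    """Write images (3-D, floats in [0,1] or uint8) or labels (1-D ints)."""
    array = np.asarray(array)
    if array.ndim == 3:
        magic = _IDX_IMAGES_MAGIC
        if array.dtype != np.uint8:
            array = np.clip(np.round(array * 255.0), 0, 255).astype(np.uint8)
    elif array.ndim == 1:
        magic = _IDX_LABELS_MAGIC
        array = array.astype(np.uint8)
    else:
        raise InvalidInputError("IDX arrays must be 3-D images or 1-D labels")
    header = struct.pack(">I", magic) + b"".join(
        struct.pack(">I", d) for d in array.shape)
    Path(path).write_bytes(header + array.tobytes())


def save_bundle_idx(bundle: ShapesBundle, out_dir: str | Path) -> None:
    """Persist a ShapesBundle as per-split IDX pairs plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    splits = {"train": bundle.train, "val": bundle.val, "test": bundle.test}
    if bundle.ood is not None:
        splits["ood"] = bundle.ood
    class_names = {}
    for name, ds in splits.items():
        write_idx(out / f"{name}-images.idx", ds.images[..., 0])
        write_idx(out / f"{name}-labels.idx", ds.labels)
        class_names[name] = list(ds.class_names)
    manifest = dict(bundle.meta)
    manifest["splits"] = sorted(splits)
    manifest["class_names"] = class_names
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_bundle_idx(in_dir: str | Path) -> ShapesBundle:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    loaded = {}
    for name in manifest["splits"]:
        images = read_idx(src / f"{name}-images.idx")[..., None]
        labels = read_idx(src / f"{name}-labels.idx")
        loaded[name] = ShapesDataset(
            images=images, labels=labels,
            class_names=tuple(manifest["class_names"][name]), split=name)
    return ShapesBundle(train=loaded["train"], val=loaded["val"],
                        test=loaded["test"], ood=loaded.get("ood"),
                        meta={k: v for k, v in manifest.items()
                              if k not in ("splits", "class_names")})
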