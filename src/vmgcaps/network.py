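"""The VMG capsule classifier: conv stem, primary capsules, two
VMG-routed convolutional capsule layers, and a class capsule layer.

Architecture, written [f, p1, p2, p3, p4]: a 2x2 convolution with stride 2
and f filters on a 32x32x1 image; a primary-capsule head of 1x1
convolutions emitting p1 pose matrices (4x4) and p1 sigmoid activations per
position; two convolutional capsule layers (p2 and p3 capsule types, 3x3
windows, stride 2, padding 1) routed by the variational mixture; and a class
layer that broadcasts one set of transform matrices over the final 4x4 grid
and routes globally into p4 = #classes capsules.

Transform matrices are shared across window offsets; each offset instead
contributes a learned 4-vector added to the translation column of its votes,
so spatial identity survives weight sharing at a fraction of the parameter
cost of per-offset matrices. The two middle layers additionally learn a
per-output-type routing prior mean. The conv stem carries no bias (the
rectifier threshold is absorbed by the primary-capsule heads). Every routed
layer owns a trainable activation cost beta_a per output type and a scalar
log-temperature for its activation sigmoid. With [32, 4, 8, 8, 10] this
network has 14,049 trainable parameters and with [32, 4, 8, 8, 4] it has
10,203.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor
from .routing import route_batched
from .vbgmm import InvalidInputError

__all__ = ["ArchitectureSpec", "VMGCapsNet", "build_model",
           "count_parameters", "spread_loss", "nll_loss",
           "export_feature_maps"]

_POSE = 4
_D = _POSE * _POSE

# embeds a 4-vector into the translation (last) column of a flattened 4x4
_COL_EMBED = np.zeros((4, _D))
for _i in range(4):
    _COL_EMBED[_i, 4 * _i + 3] = 1.0


@dataclass
class ArchitectureSpec:
    """[f, p1, p2, p3, p4] network description; p4 is the class count."""

    f: int = 32
    p: tuple[int, int, int, int] = (4, 8, 8, 10)
    input_shape: tuple[int, int, int] = (32, 32, 1)
    conv_kernel: int = 2
    conv_stride: int = 2
    caps_kernel: int = 3
    caps_stride: int = 2
    caps_pad: int = 1
    routing_iters: int = 3

    def __post_init__(self):
        self.p = tuple(int(x) for x in self.p)
        if self.f < 1 or any(x < 1 for x in self.p) or len(self.p) != 4:
            raise InvalidInputError("all filter/capsule counts must be >= 1")
        H, W, _ = self.input_shape
        for _ in range(3):  # stem + two capsule layers must leave a grid
            k, s, pd = ((self.conv_kernel, self.conv_stride, 0) if _ == 0
                        else (self.caps_kernel, self.caps_stride, self.caps_pad))
            H = (H + 2 * pd - k) // s + 1
            W = (W + 2 * pd - k) // s + 1
            if H < 1 or W < 1:
                raise InvalidInputError("input spatial size too small for "
                                        "the stride plan")
        self.final_grid = (H, W)

    @property
    def n_classes(self) -> int:
        return self.p[3]


# ---------------------------------------------------------------------------
# window extraction (shared by the stem and the capsule layers)
# ---------------------------------------------------------------------------

def _window_index(H: int, W: int, k: int, stride: int) -> tuple[np.ndarray, int, int]:
    Ho = (H - k) // stride + 1
    Wo = (W - k) // stride + 1
    r = (np.arange(Ho) * stride)[:, None, None, None] + \
        np.arange(k)[None, None, :, None]
    c = (np.arange(Wo) * stride)[None, :, None, None] + \
        np.arange(k)[None, None, None, :]
    flat = (r * W + c).reshape(-1)          # (Ho*Wo*k*k,)
    return flat, Ho, Wo


def extract_windows(x: Tensor, k: int, stride: int, pad: int) -> tuple[Tensor, int, int]:
    """(B, C, H, W) -> (B, C, Ho, Wo, k*k) sliding windows."""
    B, C, H, W = x.shape
    x = ad.pad2d(x, pad)
    H, W = H + 2 * pad, W + 2 * pad
    idx, Ho, Wo = _window_index(H, W, k, stride)
    flat = x.reshape(B, C, H * W)
    return ad.take_last(flat, idx).reshape(B, C, Ho, Wo, k * k), Ho, Wo


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class ConvStem:
    """f-filter convolution (2x2, stride 2, no bias) + rectifier."""

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator):
        cin = spec.input_shape[2]
        k = spec.conv_kernel
        fan_in = cin * k * k
        self.weight = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                           size=(cin * k * k, spec.f)))
        self.k, self.stride = k, spec.conv_stride

    def parameters(self):
        return [self.weight]

    def __call__(self, x: Tensor) -> Tensor:
        win, Ho, Wo = extract_windows(x, self.k, self.stride, 0)
        B, C = x.shape[:2]
        win = win.transpose(0, 2, 3, 1, 4).reshape(B, Ho, Wo, C * self.k * self.k)
        return ad.relu(ad.einsum("bhwf,fg->bhwg", win, self.weight))


class PrimaryCaps:
    """1x1 heads mapping f stem channels to p1 poses and activations."""

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator):
        f, p1 = spec.f, spec.p[0]
        self.p1 = p1
        sd = np.sqrt(1.0 / f)
        self.pose_w = Parameter(rng.normal(0.0, sd, size=(f, p1 * _D)))
        self.pose_b = Parameter(np.zeros(p1 * _D))
        self.act_w = Parameter(rng.normal(0.0, sd, size=(f, p1)))
        self.act_b = Parameter(np.zeros(p1))

    def parameters(self):
        return [self.pose_w, self.pose_b, self.act_w, self.act_b]

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        B, H, W, _ = x.shape
        poses = (ad.einsum("bhwf,fg->bhwg", x, self.pose_w) + self.pose_b)
        acts = ad.sigmoid(ad.einsum("bhwf,fg->bhwg", x, self.act_w) + self.act_b)
        return poses.reshape(B, H, W, self.p1, _D), acts


class _RoutedLayer:
    """Common vote-and-route machinery for conv and class capsule layers."""

    def __init__(self, p_in: int, p_out: int, n_offsets: int,
                 rng: np.random.Generator, routing_iters: int,
                 learn_mu0: bool):
        self.p_in, self.p_out = p_in, p_out
        self.routing_iters = routing_iters
        # transforms start near the identity so early votes stay in the pose
        # range the primary capsules emit; the 0.5 perturbation keeps the
        # p_out capsule types of a layer from being near-interchangeable at
        # the start (interchangeable types make routing responsibilities
        # uniform and learning slow)
        eye = np.eye(_POSE)[None, None]
        self.transform = Parameter(eye + rng.normal(0.0, 0.5,
                                                    size=(p_in, p_out, _POSE, _POSE)))
        self.vote_bias = Parameter(np.zeros((n_offsets, p_in, p_out, 4)))
        self.beta_a = Parameter(np.zeros(p_out))
        self.log_temp = Parameter(np.zeros(1))
        self.mu0 = Parameter(np.zeros((p_out, _D))) if learn_mu0 else None

    def parameters(self):
        ps = [self.transform, self.vote_bias, self.beta_a, self.log_temp]
        if self.mu0 is not None:
            ps.append(self.mu0)
        return ps

    def _votes(self, pose_windows: Tensor) -> Tensor:
        """(B?, o, p_in, 4, 4) windows -> (B?, o, p_in, p_out, 16) votes."""
        v = ad.einsum("bopij,pcjl->bopcil", pose_windows, self.transform)
        lead = v.shape[:-2]
        v = v.reshape(*lead, _D)
        bias = ad.einsum("opcd,de->opce", self.vote_bias, Tensor(_COL_EMBED))
        return v + bias

    def _route(self, votes: Tensor, acts: Tensor,
               rng: np.random.Generator | None) -> dict:
        M, n, K, D = votes.shape
        # per-capsule ELBO spread grows with the evidence n*D a capsule can
        # absorb; the inverse temperature undoes that scale (1/sqrt(nD),
        # refined by a learned log-temperature) so the activation sigmoid
        # stays responsive at every layer width
        inv_temp = ad.exp(self.log_temp) * (1.0 / np.sqrt(n * D))
        mu0 = self.mu0 if self.mu0 is not None else 0.0
        out = route_batched(votes, acts, n_iters=self.routing_iters,
                            mu0=mu0, beta_a=self.beta_a,
                            inv_temperature=1.0, rng=rng)
        out["activations"] = ad.sigmoid(
            (out["per_capsule_elbo"] - self.beta_a) * inv_temp)
        return out


class ConvCaps(_RoutedLayer):
    """Convolutional capsule layer: 3x3 windows, stride 2, VMG routing."""

    def __init__(self, p_in, p_out, spec: ArchitectureSpec,
                 rng: np.random.Generator):
        self.k, self.stride, self.pad = (spec.caps_kernel, spec.caps_stride,
                                         spec.caps_pad)
        super().__init__(p_in, p_out, self.k * self.k, rng,
                         spec.routing_iters, learn_mu0=True)

    def __call__(self, poses: Tensor, acts: Tensor,
                 rng: np.random.Generator | None = None):
        B, H, W, p_in, _ = poses.shape
        ch = poses.transpose(0, 3, 4, 1, 2).reshape(B, p_in * _D, H, W)
        win, Ho, Wo = extract_windows(ch, self.k, self.stride, self.pad)
        o = self.k * self.k
        win = (win.reshape(B, p_in, _D, Ho, Wo, o)
               .transpose(0, 3, 4, 5, 1, 2)                 # B,Ho,Wo,o,p_in,16
               .reshape(B * Ho * Wo, o, p_in, _POSE, _POSE))
        votes = self._votes(win)                            # M,o,p_in,p_out,16
        M = B * Ho * Wo
        votes = votes.transpose(0, 1, 2, 3, 4).reshape(M, o * p_in,
                                                       self.p_out, _D)
        a_ch = acts.transpose(0, 3, 1, 2)                   # B,p_in,H,W
        a_win, _, _ = extract_windows(a_ch, self.k, self.stride, self.pad)
        a_low = (a_win.transpose(0, 2, 3, 4, 1)             # B,Ho,Wo,o,p_in
                 .reshape(M, o * p_in))
        out = self._route(votes, a_low, rng)
        poses_out = out["poses"].reshape(B, Ho, Wo, self.p_out, _D)
        acts_out = out["activations"].reshape(B, Ho, Wo, self.p_out)
        return poses_out, acts_out, out


class ClassCaps(_RoutedLayer):
    """Class capsule layer: broadcasts its transform matrices over the final
    grid and routes all positions' capsules into one capsule per class."""

    def __init__(self, p_in, n_classes, grid: tuple[int, int],
                 spec: ArchitectureSpec, rng: np.random.Generator):
        self.grid = grid
        n_pos = grid[0] * grid[1]
        super().__init__(p_in, n_classes, n_pos, rng, spec.routing_iters,
                         learn_mu0=False)

    def __call__(self, poses: Tensor, acts: Tensor,
                 rng: np.random.Generator | None = None):
        B, H, W, p_in, _ = poses.shape
        n_pos = H * W
        win = poses.reshape(B, n_pos, p_in, _POSE, _POSE)
        votes = self._votes(win)                            # B,pos,p_in,c,16
        votes = votes.reshape(B, n_pos * p_in, self.p_out, _D)
        a_low = acts.reshape(B, n_pos * p_in)
        out = self._route(votes, a_low, rng)
        return out["poses"], out["activations"], out


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class VMGCapsNet:
    """Small VMG-routed capsule classifier (see module docstring)."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.stem = ConvStem(spec, rng)
        self.primary = PrimaryCaps(spec, rng)
        self.caps2 = ConvCaps(spec.p[0], spec.p[1], spec, rng)
        self.caps3 = ConvCaps(spec.p[1], spec.p[2], spec, rng)
        self.class_caps = ClassCaps(spec.p[2], spec.p[3], spec.final_grid,
                                    spec, rng)
        self._layers = [self.stem, self.primary, self.caps2, self.caps3,
                        self.class_caps]

    # -- parameter plumbing ---------------------------------------------
    def parameters(self) -> list[Parameter]:
        return [p for layer in self._layers for p in layer.parameters()]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"param_{i}": p.data.copy()
                for i, p in enumerate(self.parameters())}

    def load_state_dict(self, d: dict) -> None:
        params = self.parameters()
        if len(d) != len(params):
            raise InvalidInputError("checkpoint does not match architecture")
        for i, p in enumerate(params):
            arr = np.asarray(d[f"param_{i}"])
            if arr.shape != p.data.shape:
                raise InvalidInputError("checkpoint does not match architecture")
            p.data = arr.astype(np.float64)

    # -- forward ---------------------------------------------------------
    def forward(self, images: np.ndarray | Tensor,
                rng: np.random.Generator | None = None,
                return_maps: bool = False) -> dict:
        """Forward pass on (B, 32, 32, 1)/(B, 1, 32, 32) images in [0, 1].

        With ``rng`` given, the class layer's output poses are sampled from
        their variational posteriors (one stochastic predictive run). The
        convolutional capsule layers stay at their posterior means: most of
        their spatial positions carry little evidence, so sampling them
        draws mostly prior noise, which swamps the class signal.
        """
        x = images if isinstance(images, Tensor) else Tensor(
            preprocess_images(np.asarray(images),
                              self.spec.input_shape[:2]))
        if x.ndim != 4:
            raise InvalidInputError("images must be a 4-D batch")
        if x.shape[1] != self.spec.input_shape[2]:
            x = x.transpose(0, 3, 1, 2)
        stem_out = self.stem(x)                              # B,H,W,f
        poses1, acts1 = self.primary(stem_out)
        poses2, acts2, _ = self.caps2(poses1, acts1, None)
        poses3, acts3, _ = self.caps3(poses2, acts2, None)
        class_poses, class_acts, routing = self.class_caps(poses3, acts3, rng)
        out = {"class_activations": class_acts, "class_poses": class_poses,
               "routing": routing}
        if return_maps:
            out["maps"] = {
                "conv_stem": stem_out,
                "primary_caps": acts1,
                "conv_caps_1": acts2,
                "conv_caps_2": acts3,
                "class_caps": class_acts,
            }
        return out

    def predict_proba(self, images: np.ndarray,
                      rng: np.random.Generator | None = None) -> np.ndarray:
        """Class probabilities: activations normalized to a simplex."""
        with ad.no_grad():
            acts = self.forward(images, rng=rng)["class_activations"].data
        return acts / acts.sum(axis=1, keepdims=True)

    # -- persistence -----------------------------------------------------
    def save(self, path: str | Path, extra: dict | None = None) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state_dict())
        sidecar = {"f": self.spec.f, "p": list(self.spec.p),
                   "input_shape": list(self.spec.input_shape),
                   "routing_iters": self.spec.routing_iters}
        sidecar.update(extra or {})
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "VMGCapsNet":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        spec = ArchitectureSpec(f=meta["f"], p=tuple(meta["p"]),
                                input_shape=tuple(meta["input_shape"]),
                                routing_iters=meta.get("routing_iters", 3))
        model = cls(spec)
        with np.load(path.with_suffix(".npz")) as d:
            model.load_state_dict(dict(d))
        return model


def build_model(spec: ArchitectureSpec, seed: int = 0) -> VMGCapsNet:
    return VMGCapsNet(spec, seed=seed)


def count_parameters(model: VMGCapsNet) -> int:
    """Exact count of trainable scalars (frozen parameters excluded)."""
    return int(sum(p.data.size for p in model.parameters()
                   if p.requires_grad))


# ---------------------------------------------------------------------------
# input handling and losses
# ---------------------------------------------------------------------------

def preprocess_images(images: np.ndarray, target_hw=(32, 32)) -> np.ndarray:
    """Bring images to (B, H, W, 1) float in [0, 1]: zero-pad 28x28 inputs
    to 32x32 and collapse color channels to luminance."""
    x = np.asarray(images, dtype=np.float64)
    if x.ndim == 3:
        x = x[..., None]
    if x.shape[-1] == 3:
        x = x @ np.array([0.299, 0.587, 0.114])[:, None]
    H, W = x.shape[1:3]
    th, tw = target_hw
    if (H, W) != (th, tw):
        if H > th or W > tw:
            raise InvalidInputError(f"cannot fit {H}x{W} input into {th}x{tw}")
        ph, pw = (th - H) // 2, (tw - W) // 2
        x = np.pad(x, ((0, 0), (ph, th - H - ph), (pw, tw - W - pw), (0, 0)))
    return x


def spread_loss(class_activations, target, margin: float = 0.9):
    """Sum over wrong classes of max(0, margin - (a_t - a_i))^2.

    Accepts a single (C,) activation vector with an integer target, or a
    batched (B, C) Tensor with an array of targets (mean over the batch).
    """
    if not 0.0 < margin <= 1.0:
        raise InvalidInputError("margin must be in (0, 1]")
    if isinstance(class_activations, Tensor):
        a = class_activations
        B, C = a.shape
        t = np.asarray(target, dtype=int)
        onehot = np.zeros((B, C))
        onehot[np.arange(B), t] = 1.0
        at = ad.tsum(a * Tensor(onehot), axis=1, keepdims=True)
        viol = ad.relu(margin - (at - a))
        return ad.tsum(viol * viol * Tensor(1.0 - onehot)) * (1.0 / B)
    a = np.asarray(class_activations, dtype=np.float64)
    t = int(target)
    if not 0 <= t < a.shape[0]:
        raise InvalidInputError("target class out of range")
    viol = np.maximum(0.0, margin - (a[t] - a))
    viol[t] = 0.0
    return float(np.sum(viol ** 2))


def nll_loss(class_probabilities, target):
    """Negative log likelihood -ln p_target on a simplex vector, or the
    batch mean for a (B, C) Tensor of probabilities."""
    if isinstance(class_probabilities, Tensor):
        p = class_probabilities
        B, C = p.shape
        t = np.asarray(target, dtype=int)
        onehot = np.zeros((B, C))
        onehot[np.arange(B), t] = 1.0
        pt = ad.tsum(p * Tensor(onehot), axis=1)
        # clamp via max(p, 1e-12) expressed with relu to stay differentiable
        pt = ad.relu(pt - 1e-12) + 1e-12
        return -ad.tsum(ad.log(pt)) * (1.0 / B)
    p = np.asarray(class_probabilities, dtype=np.float64)
    t = int(target)
    if not 0 <= t < p.shape[0]:
        raise InvalidInputError("target class out of range")
    pt = p[t]
    if pt <= 0:
        warnings.warn("clamping zero probability in nll_loss", stacklevel=2)
        pt = 1e-12
    return float(-np.log(pt))


def export_feature_maps(model: VMGCapsNet, image: np.ndarray,
                        out_dir: str | Path | None = None) -> dict[str, np.ndarray]:
    """Per-layer activation grids for one image, min-max normalized to
    [0, 1]; optionally saved as grayscale PNGs (one per channel grid)."""
    img = np.asarray(image)
    if img.ndim == 2:
        img = img[None, :, :, None]
    elif img.ndim == 3:
        img = img[None]
    with ad.no_grad():
        maps = model.forward(img, return_maps=True)["maps"]
    result: dict[str, np.ndarray] = {}
    for name, t in maps.items():
        arr = t.data[0]
        lo, hi = arr.min(), arr.max()
        result[name] = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    if out_dir is not None:
        from PIL import Image
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, arr in result.items():
            grid = arr if arr.ndim == 2 else _tile(arr)
            Image.fromarray((grid * 255).astype(np.uint8)).save(
                out_dir / f"{name}.png")
    return result


def _tile(arr: np.ndarray) -> np.ndarray:
    """(H, W, C) channel maps -> one horizontal grayscale strip."""
    if arr.ndim == 1:
        return arr[None, :]
    return np.concatenate([arr[..., i] for i in range(arr.shape[-1])], axis=1)
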