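"""Exemplar-based super-resolution harness at scale factor 1.

Because the LR-ness of bundle images comes from fibre sampling rather
than pixel count, LR and HR share one pixel grid and the SR networks are
fully-convolutional *enhancement* networks: a compact FSRCNN-style
feature-shrink-map-expand architecture (whose deconvolution stage becomes
a stride-1 reconstruction convolution at scale 1) and a compact
EDSR-style residual network without batch normalisation, with a global
input skip and a zero-initialised final layer so the untrained network
is exactly the identity.

Training is stochastic and patch-based (default minibatch 54 patches of
64x64), with the L1 loss or the mixed SSIM+L1 loss

    loss = alpha * (1 - SSIM(pred, target)) + (1 - alpha) * L1,

``alpha = 0.84`` by default.  Validation patches monitor the loss and the
best-on-validation parameters are returned to avoid overfitting.
Inference runs full-size in a single pass.  Two classical baselines are
provided: unsharp-mask sharpening and Wiener deconvolution with a
Gaussian PSF (sigma 2 by default).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import InvalidArgumentError, TrainingDivergedError
from .image import CartesianImage
from .data import PatchSet
from .nn import Adam, Conv2d, ReLU, ResidualBlock, Sequential

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "build_model",
    "loss_l1",
    "loss_ssim_l1",
    "train",
    "infer",
    "baseline_sharpen",
    "baseline_wiener",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture of an enhancement network.

    ``fsrcnn_like``: ``width`` feature channels (d), ``shrink`` mapping
    channels (s), ``depth`` mapping layers (m); defaults 56/12/4.
    ``edsr_like``: ``width`` channels and ``depth`` residual blocks;
    defaults 32/4.  ``scale`` is fixed at 1.
    """

    family: str
    width: int | None = None
    depth: int | None = None
    shrink: int | None = None
    scale: int = 1

    def __post_init__(self):
        if self.family not in ("fsrcnn_like", "edsr_like"):
            raise InvalidArgumentError(f"unknown model family {self.family!r}")
        if self.scale != 1:
            raise InvalidArgumentError("only scale factor 1 is supported (shared pixel grid)")

    def resolved(self) -> "ModelSpec":
        if self.family == "fsrcnn_like":
            return ModelSpec("fsrcnn_like", self.width or 56, self.depth if self.depth is not None else 4,
                             self.shrink or 12)
        return ModelSpec("edsr_like", self.width or 32, self.depth if self.depth is not None else 4)


@dataclass
class TrainConfig:
    """Stochastic patch-training configuration."""

    minibatch: int = 54
    max_steps: int = 1500
    learning_rate: float = 1e-4
    loss: str = "l1"  # or "ssim_l1"
    alpha: float = 0.84
    seed: int = 0
    val_every: int = 25
    patience: int | None = None  # validation checks without improvement

    def __post_init__(self):
        if self.minibatch < 1:
            raise InvalidArgumentError("minibatch must be >= 1")
        if not (0.0 <= self.alpha <= 1.0):
            raise InvalidArgumentError("alpha must lie in [0, 1]")
        if self.loss not in ("l1", "ssim_l1"):
            raise InvalidArgumentError(f"unknown loss {self.loss!r}")


class SRNetwork:
    """A fully-convolutional 1-channel enhancement network.

    ``forward``/``backward`` take ``(N, H, W)`` batches; the engine runs
    channels-last float32 internally.
    """

    def __init__(self, spec: ModelSpec, seed: int = 0):
        spec = spec.resolved()
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.global_skip = spec.family == "edsr_like"
        if spec.family == "fsrcnn_like":
            d, s, m = spec.width, spec.shrink, spec.depth
            layers: list = [Conv2d(1, d, 5, rng), ReLU(), Conv2d(d, s, 1, rng), ReLU()]
            for _ in range(m):
                layers += [Conv2d(s, s, 3, rng), ReLU()]
            layers += [Conv2d(s, d, 1, rng), ReLU(), Conv2d(d, 1, 9, rng)]
            self.net = Sequential(layers)
        else:
            w, blocks = spec.width, spec.depth
            layers = [Conv2d(1, w, 3, rng)]
            layers += [ResidualBlock(w, rng) for _ in range(blocks)]
            # zero-init the final layer: the network is the identity at init
            layers += [Conv2d(w, 1, 3, rng, zero_init=True)]
            self.net = Sequential(layers)

    @property
    def receptive_field(self) -> int:
        return self.net.receptive_growth + 1

    @property
    def parameter_count(self) -> int:
        return sum(p.size for p in self.params())

    def params(self) -> list[np.ndarray]:
        return self.net.params()

    def grads(self) -> list[np.ndarray]:
        return self.net.grads()

    def forward(self, x: np.ndarray) -> np.ndarray:
        from .nn import DTYPE

        xb = np.asarray(x, dtype=DTYPE)[..., None]
        y = self.net.forward(xb)
        out = xb + y if self.global_skip else y
        return out[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        from .nn import DTYPE

        dyb = np.asarray(dy, dtype=DTYPE)[..., None]
        dx = self.net.backward(dyb)
        out = dyb + dx if self.global_skip else dx
        return out[..., 0]

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state):
            p[...] = s


def build_model(spec: ModelSpec, seed: int = 0) -> SRNetwork:
    """Instantiate a network with deterministic initialisation."""
    return SRNetwork(spec, seed=seed)


def loss_l1(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its gradient w.r.t. ``pred``."""
    if pred.shape != target.shape:
        raise InvalidArgumentError("pred/target shapes must match")
    diff = pred - target
    return float(np.abs(diff).mean()), np.sign(diff) / diff.size


def _ssim_value_and_grad(
    pred: np.ndarray,
    target: np.ndarray,
    data_range: float,
    sigma: float = 1.5,
    window: int = 11,
    k1: float = 0.01,
    k2: float = 0.03,
) -> tuple[float, np.ndarray]:
    """Mean SSIM over valid window centres and its gradient w.r.t. ``pred``.

    Operates on (..., H, W) batches.  The Gaussian window filter uses zero
    padding, which makes it self-adjoint, so the adjoint pass reuses the
    same filter.  The mean runs over centres whose window lies fully
    inside the frame, matching the reference SSIM in :mod:`pclesr.metrics`.
    """
    radius = (window - 1) // 2
    truncate = radius / sigma
    axes = (-2, -1)

    def F(z):
        return ndi.gaussian_filter(z, sigma, truncate=truncate, mode="constant", axes=axes)

    x, y = pred, target
    ux, uy = F(x), F(y)
    vx = F(x * x) - ux * ux
    vy = F(y * y) - uy * uy
    vxy = F(x * y) - ux * uy
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    A1 = 2 * ux * uy + c1
    A2 = 2 * vxy + c2
    B1 = ux * ux + uy * uy + c1
    B2 = vx + vy + c2
    S = (A1 * A2) / (B1 * B2)

    # weight map of the cropped mean
    w = np.zeros_like(S)
    core = (Ellipsis, slice(radius, S.shape[-2] - radius), slice(radius, S.shape[-1] - radius))
    n_valid = w[core].size
    if n_valid == 0:
        raise InvalidArgumentError("frame smaller than the SSIM window")
    w[core] = 1.0 / n_valid
    value = float((S * w).sum())

    inv = 1.0 / (B1 * B2)
    gu = w * (2 * uy * A2 * inv - 2 * ux * S / B1)
    gvx = w * (-S / B2)
    gvxy = w * (2 * A1 * inv)
    grad = F(gu - 2 * ux * gvx - uy * gvxy) + 2 * x * F(gvx) + y * F(gvxy)
    return value, grad


def loss_ssim_l1(
    pred: np.ndarray,
    target: np.ndarray,
    alpha: float = 0.84,
    data_range: float | None = None,
) -> tuple[float, np.ndarray]:
    """Mixed loss ``alpha*(1 - SSIM) + (1-alpha)*L1`` with gradient.

    ``data_range=None`` uses the target's peak-to-peak range (the frames
    entering training are standardised, so the range is data-dependent).
    """
    if pred.shape != target.shape:
        raise InvalidArgumentError("pred/target shapes must match")
    l1_val, l1_grad = loss_l1(pred, target)
    if alpha == 0.0:
        return l1_val, l1_grad
    if data_range is None:
        data_range = float(np.ptp(target)) or 1.0
    s_val, s_grad = _ssim_value_and_grad(pred, target, data_range)
    value = alpha * (1.0 - s_val) + (1.0 - alpha) * l1_val
    grad = -alpha * s_grad + (1.0 - alpha) * l1_grad
    return float(value), grad


def _as_batch(patches: PatchSet) -> tuple[np.ndarray, np.ndarray]:
    return patches.lr_patches, patches.hr_patches


def train(
    model: SRNetwork,
    train_patches: PatchSet,
    val_patches: PatchSet,
    config: TrainConfig,
) -> tuple[SRNetwork, pd.DataFrame]:
    """Stochastic patch-based minibatch training.

    Patch order is reshuffled each epoch with the run seed (sampling with
    replacement if the patch pool is smaller than the minibatch); the
    validation loss is evaluated every ``val_every`` steps and the
    best-on-validation parameters are restored before returning.
    History records per-step training loss and periodic validation loss.
    """
    if len(train_patches) == 0 or len(val_patches) == 0:
        raise InvalidArgumentError("patch sets must be non-empty")
    x_tr, y_tr = _as_batch(train_patches)
    x_va, y_va = _as_batch(val_patches)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.learning_rate)

    def compute_loss(pred, target):
        if config.loss == "l1":
            return loss_l1(pred, target)
        return loss_ssim_l1(pred, target, alpha=config.alpha)

    def val_loss() -> float:
        total, count = 0.0, 0
        for i in range(0, len(x_va), 32):
            xb, yb = x_va[i : i + 32], y_va[i : i + 32]
            v, _ = compute_loss(model.forward(xb), yb)
            total += v * len(xb)
            count += len(xb)
        return total / count

    n = len(x_tr)
    queue = np.empty(0, dtype=int)
    best_val = np.inf
    best_state = model.get_state()
    stale = 0
    rows = []
    for step in range(config.max_steps):
        if n < config.minibatch:
            idx = rng.integers(0, n, size=config.minibatch)
        else:
            if queue.size < config.minibatch:
                queue = np.concatenate([queue, rng.permutation(n)])
            idx, queue = queue[: config.minibatch], queue[config.minibatch :]
        pred = model.forward(x_tr[idx])
        value, dpred = compute_loss(pred, y_tr[idx])
        if not np.isfinite(value):
            raise TrainingDivergedError(step)
        model.backward(dpred)
        opt.step(model.grads())
        record = {"step": step, "train_loss": value, "val_loss": np.nan}
        if (step + 1) % config.val_every == 0 or step == config.max_steps - 1:
            v = val_loss()
            record["val_loss"] = v
            if v < best_val:
                best_val, best_state, stale = v, model.get_state(), 0
            else:
                stale += 1
                if config.patience is not None and stale > config.patience:
                    rows.append(record)
                    break
        rows.append(record)
    model.set_state(best_state)
    history = pd.DataFrame(rows)
    history.attrs["best_val_loss"] = best_val
    history.attrs["optimizer"] = f"adam(lr={config.learning_rate})"
    return model, history


def infer(model: SRNetwork, lr: CartesianImage) -> CartesianImage:
    """Full-frame single-pass enhancement; no patching at inference."""
    h, w = lr.grid_shape
    if min(h, w) < model.receptive_field:
        raise InvalidArgumentError(
            f"frame {lr.grid_shape} smaller than the receptive field {model.receptive_field}"
        )
    out = model.forward(lr.pixels[None])[0].astype(np.float64)
    out = np.where(lr.fov_mask, out, 0.0)
    return lr.with_pixels(out, {"sr_model": asdict(model.spec)})


def baseline_sharpen(image: CartesianImage, amount: float = 1.0, radius: float = 2.0) -> CartesianImage:
    """Unsharp-mask contrast enhancement, clipped to [0, 1]."""
    if amount < 0:
        raise InvalidArgumentError("amount must be >= 0")
    blurred = ndi.gaussian_filter(image.pixels, radius)
    out = np.clip(image.pixels + amount * (image.pixels - blurred), 0.0, 1.0)
    out = np.where(image.fov_mask, out, 0.0)
    return image.with_pixels(out, {"baseline": f"sharpen(amount={amount}, radius={radius})"})


def baseline_wiener(image: CartesianImage, psf_sigma: float = 2.0, nsr: float = 0.01) -> CartesianImage:
    """Frequency-domain Wiener deconvolution with a Gaussian PSF.

    The Gaussian transfer function ``H = exp(-2 pi^2 sigma^2 |f|^2)`` is
    real and positive; the filter gain is ``H / (H^2 + nsr)`` with a
    constant noise-to-signal ratio.
    """
    if psf_sigma <= 0:
        raise InvalidArgumentError("psf_sigma must be positive")
    if nsr < 0:
        raise InvalidArgumentError("nsr must be >= 0")
    h, w = image.grid_shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    H = np.exp(-2.0 * np.pi**2 * psf_sigma**2 * (fy**2 + fx**2))
    G = H / (H * H + nsr)
    out = np.real(np.fft.ifft2(G * np.fft.fft2(image.pixels)))
    out = np.where(image.fov_mask, out, 0.0)
    return image.with_pixels(out, {"baseline": f"wiener(psf_sigma={psf_sigma}, nsr={nsr})"})


def save_checkpoint(
    ckpt_dir: str | Path,
    model: SRNetwork,
    config: TrainConfig,
    history: pd.DataFrame | None = None,
) -> Path:
    """Checkpoint directory: weights + ModelSpec/TrainConfig JSON + history CSV."""
    d = Path(ckpt_dir)
    d.mkdir(parents=True, exist_ok=True)
    np.savez(d / "weights.npz", **{f"p{i}": p for i, p in enumerate(model.params())})
    (d / "model_spec.json").write_text(json.dumps(asdict(model.spec)))
    (d / "train_config.json").write_text(json.dumps(asdict(config)))
    if history is not None:
        history.to_csv(d / "history.csv", index=False)
    return d


def load_checkpoint(ckpt_dir: str | Path) -> tuple[SRNetwork, TrainConfig]:
    d = Path(ckpt_dir)
    spec = ModelSpec(**json.loads((d / "model_spec.json").read_text()))
    config = TrainConfig(**json.loads((d / "train_config.json").read_text()))
    model = SRNetwork(spec, seed=0)
    with np.load(d / "weights.npz") as z:
        model.set_state([z[f"p{i}"] for i in range(len(model.params()))])
    return model, config
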