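"""Residual-network synthesis of full-view sinograms from few-view scans.

A few-view sinogram (15 projections over 180°) is first upsampled to the
full-view angle grid (30 projections) by linear angular interpolation; a
residual convolutional network then predicts a correction on top of the
interpolation. The architecture: one 3×3 convolution with 64 filters, four
residual blocks of three 3×3/64 convolutions each with an identity shortcut
spanning the three layers, two 3×3/64 convolutions, one 3×3/32 convolution,
and a single-filter 3×3 output convolution; ReLU after every layer except
the output. Training minimizes the composite loss

    L = α·(1 − SSIM(pred, target)) + (1 − α)·‖pred − target‖₁ / N

on paired few-view/full-view simulated sinograms; the three detector
channels are independent single-channel samples sharing weights.

The network runs on the in-repo autodiff engine (no GPU framework); the
output convolution is initialized near zero so an untrained model starts at
(approximately) the interpolation baseline, and forcing the output layer to
zero reproduces the interpolation exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import h5py
import numpy as np

from .autodiff import Tensor, conv2d, mean, mean_abs, relu
from .forward import Sinogram

__all__ = [
    "NetConfig", "TrainingPair", "TrainedModel", "composite_loss",
    "upsample_views", "init_params", "net_forward", "synthesize_full_view",
    "train", "save_model", "load_model",
]


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass(frozen=True)
class NetConfig:
    """Architecture and loss configuration of the view-synthesis network.

    The layer counts are the fixed architecture described in the module
    docstring; ``loss_alpha`` weights SSIM vs L1 in the composite loss;
    ``upsample_mode`` is the pre-interpolation along the view axis.
    """

    n_filters: int = 64
    n_residual_blocks: int = 4
    block_depth: int = 3
    tail_filters: tuple[int, ...] = (64, 64, 32)
    kernel_size: int = 3
    loss_alpha: float = 0.8
    upsample_mode: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.loss_alpha <= 1.0:
            raise ValueError("loss_alpha must lie in [0, 1]")
        if self.upsample_mode != "linear":
            raise ValueError("only linear view upsampling is implemented")


@dataclass(frozen=True)
class TrainingPair:
    """Paired few-view and full-view sinograms of the same phantom scan."""

    few: Sinogram
    full: Sinogram

    def __post_init__(self) -> None:
        vf, tf, df = self.few.shape
        vF, tF, dF = self.full.shape
        if (tf, df) != (tF, dF) or vF != 2 * vf:
            raise ValueError(
                f"incompatible pair shapes {self.few.shape} / {self.full.shape}")
        if not np.allclose(self.few.angles, self.full.angles[::2]):
            raise ValueError("few-view angles are not nested in full-view angles")


@dataclass
class TrainedModel:
    """Network parameters plus everything inference needs.

    ``params`` is the flat list of (weight, bias) arrays in layer order;
    ``normalization`` records the per-sinogram scaling scheme so inference
    is self-contained; ``history`` holds per-epoch train/validation losses.
    """

    params: list[np.ndarray]
    config: NetConfig
    history: dict = field(default_factory=lambda: {"train": [], "val": []})
    normalization: dict = field(default_factory=lambda:
                                {"scheme": "sqrt-of-per-sinogram-max"})
    seed: int = 0
    epochs_run: int = 0


# ---------------------------------------------------------------------------
# composite loss

def _ssim_tensor(x: Tensor, y: Tensor, data_range: float = 1.0,
                 win: int = 7) -> Tensor:
    """Mean local SSIM over the valid window region (uniform window)."""
    c1 = np.float32((0.01 * data_range) ** 2)
    c2 = np.float32((0.03 * data_range) ** 2)
    kernel = Tensor(np.full((1, 1, win, win), 1.0 / (win * win),
                            dtype=np.float32))

    def box(t: Tensor) -> Tensor:
        return conv2d(t, kernel, pad=0)

    mx, my = box(x), box(y)
    sxx = box(x * x) - mx * mx
    syy = box(y * y) - my * my
    sxy = box(x * y) - mx * my
    num = (2.0 * mx * my + c1) * (2.0 * sxy + c2)
    den = (mx * mx + my * my + c1) * (sxx + syy + c2)
    return mean(num / den)


def _composite_loss_tensor(pred: Tensor, target: Tensor, alpha: float,
                           data_range: float = 1.0) -> Tensor:
    l1 = mean_abs(pred - target)
    if alpha == 0.0:
        return l1
    ssim_term = 1.0 - _ssim_tensor(pred, target, data_range)
    if alpha == 1.0:
        return ssim_term
    return alpha * ssim_term + (1.0 - alpha) * l1


def composite_loss(prediction: np.ndarray, target: np.ndarray,
                   alpha: float, data_range: float = 1.0) -> float:
    """α·(1 − SSIM) + (1 − α)·L1 between image batches.

    Zero iff prediction equals target, for every α in [0, 1]. Accepts 2D
    images or (B, H, W) batches; SSIM uses a uniform 7×7 window over the
    valid region.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    p = np.asarray(prediction, dtype=np.float32)
    t = np.asarray(target, dtype=np.float32)
    if p.shape != t.shape:
        raise ValueError("prediction/target shapes differ")
    if p.ndim == 2:
        p, t = p[None], t[None]
    loss = _composite_loss_tensor(Tensor(p[..., None]), Tensor(t[..., None]),
                                  alpha, data_range)
    return float(loss.data)


# ---------------------------------------------------------------------------
# view-axis upsampling

def upsample_views(few: Sinogram, target_n_views: int | None = None,
                   mode: str = "linear") -> Sinogram:
    """Double the number of views by linear interpolation along the view axis.

    The original views are preserved exactly at their angles; each inserted
    view is the mean of its two angular neighbours. At the 180° wrap the
    neighbour of the last inserted view is view 0 flipped along the
    translation axis (parallel-beam sinogram periodicity).
    """
    if mode != "linear":
        raise ValueError(f"unsupported upsample mode {mode!r}")
    V, T, D = few.shape
    if target_n_views is None:
        target_n_views = 2 * V
    if target_n_views != 2 * V:
        raise ValueError("target angle grid must be a 2x superset of the "
                         "few-view grid")
    step = np.diff(few.angles).mean() if V > 1 else 180.0
    out = np.empty((2 * V, T, D))
    out[0::2] = few.values
    out[1:-1:2] = 0.5 * (few.values[:-1] + few.values[1:])
    out[-1] = 0.5 * (few.values[-1] + few.values[0, ::-1, :])
    angles = np.empty(2 * V)
    angles[0::2] = few.angles
    angles[1::2] = few.angles + step / 2
    return Sinogram(values=np.clip(out, 0.0, None), angles=angles,
                    offsets=few.offsets, detector_offsets=few.detector_offsets,
                    noise=dict(few.noise))


# ---------------------------------------------------------------------------
# network

def _layer_shapes(cfg: NetConfig) -> list[tuple[int, int]]:
    """(out_channels, in_channels) per convolution, in order."""
    f, k = cfg.n_filters, cfg.kernel_size
    shapes = [(f, 1)]                                   # stem
    for _ in range(cfg.n_residual_blocks):
        shapes += [(f, f)] * cfg.block_depth
    prev = f
    for t in cfg.tail_filters:
        shapes.append((t, prev))
        prev = t
    shapes.append((1, prev))                            # output conv
    return shapes


def init_params(cfg: NetConfig) -> list[np.ndarray]:
    """He-normal seeded initialization.

    The output convolution gets a much smaller scale (std 0.01) so the
    initial correction is near zero — the network starts close to the
    interpolation baseline without the optimization plateau an exactly-zero
    output layer causes (zero output weights gate the gradient to every
    earlier layer). Zeroing the final weight/bias pair by hand makes the
    network reproduce the interpolation exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    k = cfg.kernel_size
    params: list[np.ndarray] = []
    shapes = _layer_shapes(cfg)
    for li, (cout, cin) in enumerate(shapes):
        fan_in = cin * k * k
        std = np.sqrt(2.0 / fan_in) if li < len(shapes) - 1 else 0.01
        w = rng.normal(0.0, std, (cout, cin, k, k)).astype(np.float32)
        params += [w, np.zeros(cout, dtype=np.float32)]
    return params


def net_forward(params: list, cfg: NetConfig, x: Tensor) -> Tensor:
    """Residual-network correction for a (B, V, T, 1) input batch."""
    tensors = [p if isinstance(p, Tensor) else Tensor(p) for p in params]

    def layer(h: Tensor, pos: int, act: bool = True) -> Tensor:
        out = conv2d(h, tensors[2 * pos], tensors[2 * pos + 1],
                     pad=cfg.kernel_size // 2)
        return relu(out) if act else out

    h = layer(x, 0)                                      # stem
    pos = 1
    for _ in range(cfg.n_residual_blocks):
        shortcut = h
        for d in range(cfg.block_depth):
            h = layer(h, pos, act=(d < cfg.block_depth - 1))
            pos += 1
        h = relu(h + shortcut)                           # identity shortcut
    for _ in cfg.tail_filters:
        h = layer(h, pos)
        pos += 1
    return layer(h, pos, act=False)                      # output conv


def synthesize_full_view(model: TrainedModel, few: Sinogram) -> Sinogram:
    """Map a few-view sinogram to a synthesized full-view sinogram.

    Pipeline: linear view upsampling, per-sinogram max normalization, the
    residual correction, rescaling, and clipping at zero. Output has twice
    the input's view count with the same translations and detectors.
    """
    up = upsample_views(few)
    scale = float(few.values.max())
    if scale <= 0:
        return up
    x = np.sqrt(up.values / scale).transpose(2, 0, 1)[..., None] \
        .astype(np.float32)
    corr = net_forward(model.params, model.config, Tensor(x)).data
    out = np.clip(x + corr, 0.0, None)[..., 0].transpose(1, 2, 0) ** 2 * scale
    return Sinogram(values=out, angles=up.angles, offsets=up.offsets,
                    detector_offsets=up.detector_offsets,
                    noise={"model": "synthesized"})


# ---------------------------------------------------------------------------
# training

def _pair_samples(pair: TrainingPair) -> tuple[np.ndarray, np.ndarray]:
    """Per-detector normalized (input, target) stacks of shape (D, 2V, T, 1).

    Working domain of the network: sqrt(value / few-view max). Diffusive
    decay makes raw readings span decades; square-root compression evens
    out the loss contribution across the sinogram and stabilizes training.
    """
    scale = float(pair.few.values.max())
    scale = scale if scale > 0 else 1.0
    up = np.sqrt(upsample_views(pair.few).values / scale)
    full = np.sqrt(pair.full.values / scale)
    x = up.transpose(2, 0, 1)[..., None].astype(np.float32)
    y = full.transpose(2, 0, 1)[..., None].astype(np.float32)
    return x, y


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def train(pairs: list[TrainingPair], config: NetConfig | None = None,
          epochs: int = 200, lr: float = 1e-3, batch_size: int = 8,
          split: tuple[float, float, float] = (0.8, 0.1, 0.1),
          seed: int = 0, verbose: bool = False) -> TrainedModel:
    """Train the view-synthesis network on paired simulated sinograms.

    Samples are the individual detector channels of each pair (shared
    weights). The train/validation/test split is by pair (phantom), shuffled
    with ``seed``; per-epoch mean train loss and validation loss are
    recorded. Deterministic given (seed, config). Raises
    :class:`DivergenceError` when the loss goes non-finite.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two training pairs")
    cfg = config or NetConfig(seed=seed)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    n_train = max(1, int(round(split[0] * len(pairs))))
    n_val = max(1, int(round(split[1] * len(pairs)))) \
        if len(pairs) - n_train >= 2 else 0
    train_idx = order[:n_train]
    val_idx = order[n_train:n_train + n_val]

    def stack(indices) -> tuple[np.ndarray, np.ndarray]:
        xs, ys = zip(*(_pair_samples(pairs[i]) for i in indices))
        return np.concatenate(xs), np.concatenate(ys)

    x_train, y_train = stack(train_idx)
    x_val, y_val = stack(val_idx) if len(val_idx) else (None, None)

    params = init_params(cfg)
    opt = _Adam(params, lr)
    history: dict = {"train": [], "val": []}
    n = x_train.shape[0]
    for epoch in range(epochs):
        perm = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, batch_size):
            sel = perm[start:start + batch_size]
            wb = [Tensor(p, requires_grad=True) for p in params]
            pred = Tensor(x_train[sel]) + net_forward(wb, cfg,
                                                      Tensor(x_train[sel]))
            loss = _composite_loss_tensor(pred, Tensor(y_train[sel]),
                                          cfg.loss_alpha)
            lv = float(loss.data)
            if not np.isfinite(lv):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            loss.backward()
            opt.step(params, [t.grad for t in wb])
            epoch_losses.append(lv)
        history["train"].append(float(np.mean(epoch_losses)))
        if x_val is not None:
            pred = Tensor(x_val) + net_forward(params, cfg, Tensor(x_val))
            history["val"].append(float(_composite_loss_tensor(
                pred, Tensor(y_val), cfg.loss_alpha).data))
        if verbose:
            msg = f"epoch {epoch + 1}/{epochs} train {history['train'][-1]:.5f}"
            if history["val"]:
                msg += f" val {history['val'][-1]:.5f}"
            print(msg)
    return TrainedModel(params=params, config=cfg, history=history,
                        seed=seed, epochs_run=epochs)


# ---------------------------------------------------------------------------
# checkpoint I/O

def save_model(model: TrainedModel, path) -> None:
    """Write a self-contained checkpoint (parameters + config + history)."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "xlct-model-v1"
        f.attrs["seed"] = model.seed
        f.attrs["epochs_run"] = model.epochs_run
        g = f.create_group("params")
        for i, p in enumerate(model.params):
            g.create_dataset(f"p{i:03d}", data=p)
        c = f.create_group("config")
        for k, v in asdict(model.config).items():
            c.attrs[k] = v
        h = f.create_group("history")
        h.create_dataset("train", data=np.asarray(model.history["train"]))
        h.create_dataset("val", data=np.asarray(model.history["val"]))
        nrm = f.create_group("normalization")
        for k, v in model.normalization.items():
            nrm.attrs[k] = v


def load_model(path) -> TrainedModel:
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "xlct-model-v1":
            raise ValueError(f"{path}: not an xlct model checkpoint")
        params = [f["params"][k][()] for k in sorted(f["params"].keys())]
        ca = dict(f["config"].attrs)
        cfg = NetConfig(
            n_filters=int(ca["n_filters"]),
            n_residual_blocks=int(ca["n_residual_blocks"]),
            block_depth=int(ca["block_depth"]),
            tail_filters=tuple(int(t) for t in ca["tail_filters"]),
            kernel_size=int(ca["kernel_size"]),
            loss_alpha=float(ca["loss_alpha"]),
            upsample_mode=str(ca["upsample_mode"]),
            seed=int(ca["seed"]),
        )
        history = {"train": list(f["history"]["train"][()]),
                   "val": list(f["history"]["val"][()])}
        model = TrainedModel(params=params, config=cfg, history=history,
                             seed=int(f.attrs["seed"]),
                             epochs_run=int(f.attrs["epochs_run"]))
        model.normalization = {k: (v.item() if hasattr(v, "item") else v)
                               for k, v in f["normalization"].attrs.items()}
        return model
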