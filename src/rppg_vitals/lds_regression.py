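"""Label-distribution-smoothing (LDS) weighted regression on rPPG windows.

Deep imbalanced regression: continuous labels (blood pressure, hemoglobin)
are unevenly represented, so plain MSE training over-fits the dense middle
of the label range and under-serves the tails. LDS builds the empirical
label histogram, convolves it with a triangular kernel to obtain an
*effective* label density, and weights each training sample by the inverse
of that smoothed density (rescaled to mean one). Training minimises the
weighted MSE with Adam on a 1-D U-Net over the stacked per-ROI RGB traces
of each 10-second window; separate models are trained per vital sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._unet import Adam, UNet1d
from .preprocess import MeasurementWindow
from .synthetic_data import ROI_NAMES

__all__ = [
    "LDSConfig",
    "LDSWeights",
    "RegressorConfig",
    "TrainedModel",
    "build_label_histogram",
    "smooth_label_density",
    "compute_sample_weights",
    "lds_weights",
    "weighted_mse",
    "build_regressor",
    "windows_to_arrays",
    "train",
    "predict",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class LDSConfig:
    """Binning and smoothing controls for label distribution smoothing.

    Default bin width 1.0 suits blood pressure in mm Hg; use 0.1 for
    hemoglobin in g/dL. ``kernel_halfwidth`` is in bins.
    """

    bin_width: float = 1.0
    kernel: str = "triangular"
    kernel_halfwidth: int = 5
    reweight: str = "inverse"
    weight_normalization: str = "mean_one"

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.kernel_halfwidth < 0:
            raise ValueError("kernel_halfwidth must be >= 0")
        if self.kernel != "triangular":
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        if self.reweight != "inverse" or self.weight_normalization != "mean_one":
            raise ValueError("only inverse reweighting with mean_one normalization is supported")


@dataclass
class LDSWeights:
    bin_edges: np.ndarray
    raw_counts: np.ndarray
    smoothed_density: np.ndarray
    sample_weights: np.ndarray


@dataclass(frozen=True)
class RegressorConfig:
    """Architecture and optimisation settings for one vital-sign model."""

    target: str = "sbp"  # sbp | dbp | hb
    architecture: str = "unet1d"
    depth: int = 3
    base_channels: int = 16
    input_rois: tuple = ROI_NAMES  # which ROI traces are stacked as channels
    optimizer: str = "adam"
    learning_rate: float = 0.001
    batch_size: int = 64
    epochs: int = 300
    loss: str = "weighted_mse"
    clamp_range: tuple | None = None  # (low, high) in label units, applied at predict
    seed: int = 0

    def __post_init__(self):
        if self.target not in ("sbp", "dbp", "hb"):
            raise ValueError(f"unknown target {self.target!r}")
        if self.architecture != "unet1d" or self.optimizer != "adam" or self.loss != "weighted_mse":
            raise ValueError("unsupported architecture/optimizer/loss")
        if min(self.depth, self.base_channels, self.batch_size, self.epochs) < 1:
            raise ValueError("hyperparameters must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")


@dataclass
class TrainedModel:
    target: str
    network: UNet1d
    x_scale: np.ndarray  # per-channel std used to standardize inputs
    y_mean: float
    y_sd: float
    training_history: list  # per-epoch dicts with train/validation loss
    config: RegressorConfig

    @property
    def n_parameters(self) -> int:
        return self.network.n_parameters


# --------------------------------------------------------------------------
# label distribution smoothing
# --------------------------------------------------------------------------

def build_label_histogram(labels, lds_config: LDSConfig):
    """Left-closed right-open equal-width bins spanning [min, max] of labels.

    The grid starts at the minimum label and extends one bin past the
    maximum, so every bin is right-open and every label (including the
    maximum) is counted. Returns (bin_edges, raw_counts); counts sum to
    ``len(labels)``.
    """
    labels = np.asarray(labels, dtype=float)
    if labels.size == 0:
        raise ValueError("no labels")
    lo, hi = labels.min(), labels.max()
    n_bins = int(np.floor((hi - lo) / lds_config.bin_width)) + 1
    edges = lo + lds_config.bin_width * np.arange(n_bins + 1)
    if edges[-1] <= hi:  # guard against float round-down: keep every bin right-open
        edges = np.append(edges, edges[-1] + lds_config.bin_width)
    counts, _ = np.histogram(labels, bins=edges)
    return edges, counts.astype(float)


def smooth_label_density(raw_counts, lds_config: LDSConfig) -> np.ndarray:
    """Convolve bin counts with a symmetric triangular kernel (zero-padded edges).

    Kernel weights are proportional to ``h + 1 - |offset|`` for offsets in
    [-h, h], normalised to sum to one; h = 0 reduces to the identity.
    """
    raw_counts = np.asarray(raw_counts, dtype=float)
    h = lds_config.kernel_halfwidth
    if h == 0:
        return raw_counts.copy()
    offsets = np.arange(-h, h + 1)
    kernel = (h + 1 - np.abs(offsets)).astype(float)
    kernel /= kernel.sum()
    return np.convolve(raw_counts, kernel, mode="same")


def compute_sample_weights(labels, bin_edges, smoothed_density, lds_config: LDSConfig):
    """Per-sample weights inversely proportional to smoothed bin density, mean one.

    Bins with zero smoothed density are floored at the smallest positive
    density before inversion, so no weight is infinite.
    """
    labels = np.asarray(labels, dtype=float)
    smoothed = np.asarray(smoothed_density, dtype=float)
    if not (smoothed > 0).any():
        raise ValueError("all-zero smoothed density")
    dens = smoothed.copy()
    dens[dens <= 0] = dens[dens > 0].min()
    idx = np.clip(np.searchsorted(bin_edges, labels, side="right") - 1, 0, len(dens) - 1)
    w = 1.0 / dens[idx]
    return w / w.mean()


def lds_weights(labels, lds_config: LDSConfig) -> LDSWeights:
    """Histogram -> triangular smoothing -> inverse mean-one weights, in one call."""
    edges, counts = build_label_histogram(labels, lds_config)
    smoothed = smooth_label_density(counts, lds_config)
    weights = compute_sample_weights(labels, edges, smoothed, lds_config)
    return LDSWeights(bin_edges=edges, raw_counts=counts,
                      smoothed_density=smoothed, sample_weights=weights)


def weighted_mse(predictions, targets, weights) -> float:
    """sum_i w_i (pred_i - target_i)^2 / sum_i w_i (weight-scale invariant)."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(targets, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (p.shape == t.shape == w.shape):
        raise ValueError("predictions, targets and weights must have equal length")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    return float(np.sum(w * (p - t) ** 2) / np.sum(w))


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------

def windows_to_arrays(windows, target: str, input_rois=ROI_NAMES):
    """Stack per-window ROI RGB traces into (N, C, L) and pull labels as (N,).

    Channels are ROI-major (ROI0-R, ROI0-G, ROI0-B, ROI1-R, ...). Each
    channel is linearly detrended per window, removing the skin-tone
    dependent baseline so the pulsatile component carries the signal.
    """
    from scipy.signal import detrend

    if not windows:
        raise ValueError("no windows")
    xs, ys = [], []
    for w in windows:
        chans = np.concatenate([w.roi_traces[roi].T for roi in input_rois], axis=0)
        xs.append(detrend(chans, axis=1))
        label = getattr(w.labels, target) if w.labels is not None else np.nan
        ys.append(label)
    return np.asarray(xs, dtype=np.float32), np.asarray(ys, dtype=float)


def build_regressor(config: RegressorConfig, input_length: int | None = None,
                    n_channels: int | None = None) -> UNet1d:
    """Construct the 1-D U-Net with deterministic seeded initialisation."""
    if n_channels is None:
        n_channels = 3 * len(config.input_rois)
    return UNet1d(
        in_channels=n_channels,
        depth=config.depth,
        base_channels=config.base_channels,
        input_length=input_length,
        seed=config.seed,
    )


class TrainingDiverged(RuntimeError):
    pass


def train(model: UNet1d, train_windows, val_windows, lds_weights_, config: RegressorConfig,
          ) -> TrainedModel:
    """Fit one vital-sign regressor with Adam on the LDS-weighted MSE.

    Inputs are standardized by per-channel standard deviation of the
    (detrended) training traces; labels are z-scored by training mean/SD and
    the transform is inverted at prediction time. The loss recorded in the
    history is on the standardized label scale. Per-epoch shuffling is
    seeded, so a run is bit-reproducible on one thread.
    """
    x_tr, y_tr = windows_to_arrays(train_windows, config.target, config.input_rois)
    weights = np.asarray(
        lds_weights_.sample_weights if isinstance(lds_weights_, LDSWeights) else lds_weights_,
        dtype=float,
    )
    if len(weights) != len(x_tr):
        raise ValueError("lds weights must align with training windows")

    x_scale = x_tr.std(axis=(0, 2)) + 1e-8  # per-channel
    y_mean, y_sd = float(y_tr.mean()), float(y_tr.std() + 1e-12)
    xs = x_tr / x_scale[None, :, None]
    ys = ((y_tr - y_mean) / y_sd).astype(np.float32)
    ws = weights.astype(np.float32)

    have_val = val_windows is not None and len(val_windows) > 0
    if have_val:
        x_va, y_va = windows_to_arrays(val_windows, config.target, config.input_rois)
        xv = x_va / x_scale[None, :, None]
        yv = ((y_va - y_mean) / y_sd).astype(np.float32)

    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    n = len(xs)
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_wsum = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb, wb = xs[idx], ys[idx], ws[idx]
            pred = model.forward(xb)
            resid = pred - yb
            wsum = wb.sum()
            loss = float(np.sum(wb * resid ** 2) / wsum)
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, target {config.target}"
                )
            if config.learning_rate > 0:
                model.backward((2.0 * wb * resid / wsum).astype(np.float32))
                opt.step(model.gradients())
            epoch_loss += loss * wsum
            epoch_wsum += wsum
        entry = {"epoch": epoch, "train_loss": float(epoch_loss / epoch_wsum)}
        if have_val:
            pv = _forward_batched(model, xv, config.batch_size)
            entry["val_loss"] = float(np.mean((pv - yv) ** 2))
        history.append(entry)

    return TrainedModel(
        target=config.target,
        network=model,
        x_scale=x_scale,
        y_mean=y_mean,
        y_sd=y_sd,
        training_history=history,
        config=config,
    )


def _forward_batched(net: UNet1d, x: np.ndarray, batch_size: int) -> np.ndarray:
    outs = [net.forward(x[i:i + batch_size]) for i in range(0, len(x), batch_size)]
    return np.concatenate(outs)


def predict(model: TrainedModel, windows) -> np.ndarray:
    """Per-window estimates in label units, order preserved."""
    x, _ = windows_to_arrays(windows, model.target, model.config.input_rois)
    expected = 3 * len(model.config.input_rois)
    if x.shape[1] != expected:
        raise ValueError(f"expected {expected} input channels, got {x.shape[1]}")
    xs = x / model.x_scale[None, :, None]
    z = _forward_batched(model.network, xs, model.config.batch_size)
    y = z * model.y_sd + model.y_mean
    if model.config.clamp_range is not None:
        y = np.clip(y, *model.config.clamp_range)
    return y


def save_model(model: TrainedModel, path) -> None:
    """Write a self-describing checkpoint: config snapshot, scalers, weights."""
    import dataclasses
    import json

    meta = {
        "target": model.target,
        "y_mean": model.y_mean,
        "y_sd": model.y_sd,
        "config": dataclasses.asdict(model.config),
        "history": model.training_history,
    }
    params = {f"param_{i}": p for i, p in enumerate(model.network.parameters())}
    np.savez(path, meta=json.dumps(meta), x_scale=model.x_scale, **params)


def load_model(path) -> TrainedModel:
    """Rebuild a :class:`TrainedModel` from a checkpoint written by ``save_model``."""
    import json

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        cfg_dict = meta["config"]
        cfg_dict["input_rois"] = tuple(cfg_dict["input_rois"])
        if cfg_dict.get("clamp_range") is not None:
            cfg_dict["clamp_range"] = tuple(cfg_dict["clamp_range"])
        config = RegressorConfig(**cfg_dict)
        net = build_regressor(config)
        n_params = len(net.parameters())
        net.set_parameters([data[f"param_{i}"] for i in range(n_params)])
        return TrainedModel(
            target=meta["target"],
            network=net,
            x_scale=data["x_scale"],
            y_mean=meta["y_mean"],
            y_sd=meta["y_sd"],
            training_history=meta["history"],
            config=config,
        )
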