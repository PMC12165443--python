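"""Windowing, quality filtering, extreme-label exclusion and dataset splitting.

A session recording is cut into non-overlapping 10-second windows, each an
independent "data point" carrying its patient's reference vitals. Windows
where the face was insufficiently centered are dropped, as are windows with
extreme blood-pressure labels (SBP <=80 or >=180, DBP <=60 or >=130 mm Hg),
and the surviving windows are shuffled and split into train/validation/test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .synthetic_data import SessionRecording

__all__ = [
    "VitalLabels",
    "MeasurementWindow",
    "PreprocessConfig",
    "DatasetSplit",
    "extract_roi_trace",
    "segment_windows",
    "quality_filter",
    "exclude_extremes",
    "split_dataset",
]


@dataclass(frozen=True)
class VitalLabels:
    sbp: float  # mm Hg
    dbp: float  # mm Hg
    hb: float | None = None  # g/dL

    def __post_init__(self):
        if self.sbp <= self.dbp:
            raise ValueError(f"sbp ({self.sbp}) must exceed dbp ({self.dbp})")
        if self.dbp <= 0 or (self.hb is not None and self.hb <= 0):
            raise ValueError("vitals must be positive")


@dataclass
class MeasurementWindow:
    patient_id: str
    session_index: int
    window_index: int  # 0-based within the session
    roi_traces: dict  # ROI name -> (window_frames, 3) array
    labels: VitalLabels | None
    centered: np.ndarray  # per-frame flags for this window
    quality_pass: bool = True

    @property
    def centered_fraction(self) -> float:
        return float(np.mean(self.centered))


@dataclass(frozen=True)
class PreprocessConfig:
    window_seconds: float = 10.0
    sbp_low: float = 80.0
    sbp_high: float = 180.0
    dbp_low: float = 60.0
    dbp_high: float = 130.0
    centered_fraction_min: float = 0.8
    split_proportions: tuple = (0.70, 0.15, 0.15)
    # if True a window is extreme only when BOTH vitals are out of range
    # (the literal conjunction reading); default is the OR reading, which
    # actually removes outliers.
    extreme_requires_both: bool = False
    patient_grouped_split: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.window_seconds <= 0:
            raise ValueError("window_seconds must be positive")
        if not (self.sbp_low < self.sbp_high and self.dbp_low < self.dbp_high):
            raise ValueError("low thresholds must be below high thresholds")
        p = self.split_proportions
        if len(p) != 3 or any(x < 0 for x in p) or not np.isclose(sum(p), 1.0):
            raise ValueError("split_proportions must be three non-negatives summing to 1")
        if not 0.0 <= self.centered_fraction_min <= 1.0:
            raise ValueError("centered_fraction_min must be in [0, 1]")


@dataclass(frozen=True)
class DatasetSplit:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray

    def sizes(self) -> tuple:
        return len(self.train), len(self.validation), len(self.test)


def extract_roi_trace(frame_pixels: np.ndarray, roi_mask: np.ndarray) -> tuple:
    """Spatial mean of each RGB channel over a masked region of one frame.

    ``frame_pixels`` is (H, W, 3); ``roi_mask`` is a (H, W) boolean mask.
    """
    frame_pixels = np.asarray(frame_pixels)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if frame_pixels.ndim != 3 or frame_pixels.shape[2] != 3:
        raise ValueError("frame_pixels must be (H, W, 3)")
    if roi_mask.shape != frame_pixels.shape[:2]:
        raise ValueError("mask shape must match frame")
    if not roi_mask.any():
        raise ValueError("empty ROI mask")
    means = frame_pixels[roi_mask].mean(axis=0)
    return float(means[0]), float(means[1]), float(means[2])


def segment_windows(
    recording: SessionRecording,
    config: PreprocessConfig,
    labels: VitalLabels | None = None,
) -> list:
    """Cut a recording into consecutive non-overlapping windows.

    Yields ``floor(duration / window_seconds)`` windows; a trailing
    remainder shorter than one window is discarded.
    """
    win_frames = int(round(recording.frame_rate * config.window_seconds))
    n_frames = recording.n_frames
    n_windows = int(np.floor(recording.duration / config.window_seconds))
    if n_windows == 0:
        warnings.warn(
            f"recording {recording.patient_id}/s{recording.session_index} shorter "
            f"than one window ({recording.duration} s < {config.window_seconds} s)",
            stacklevel=2,
        )
        return []
    windows = []
    for w in range(n_windows):
        sl = slice(w * win_frames, (w + 1) * win_frames)
        if sl.stop > n_frames:
            break
        windows.append(
            MeasurementWindow(
                patient_id=recording.patient_id,
                session_index=recording.session_index,
                window_index=w,
                roi_traces={roi: tr[sl] for roi, tr in recording.roi_traces.items()},
                labels=labels,
                centered=recording.centered[sl],
            )
        )
    return windows


def quality_filter(windows: list, config: PreprocessConfig) -> list:
    """Keep windows whose fraction of face-centered frames meets the threshold."""
    retained = []
    for w in windows:
        ok = w.centered_fraction >= config.centered_fraction_min
        w.quality_pass = bool(ok)
        if ok:
            retained.append(w)
    return retained


def _is_extreme(sbp: float, dbp: float, config: PreprocessConfig) -> bool:
    sbp_out = sbp <= config.sbp_low or sbp >= config.sbp_high
    dbp_out = dbp <= config.dbp_low or dbp >= config.dbp_high
    return (sbp_out and dbp_out) if config.extreme_requires_both else (sbp_out or dbp_out)


def exclude_extremes(windows: list, config: PreprocessConfig) -> list:
    """Drop windows whose BP labels fall in the extreme ranges (boundaries drop)."""
    for w in windows:
        if w.labels is None:
            raise ValueError(f"window {w.patient_id}/{w.window_index} has no labels")
    return [w for w in windows if not _is_extreme(w.labels.sbp, w.labels.dbp, config)]


def split_dataset(n_windows: int, config: PreprocessConfig, groups=None) -> DatasetSplit:
    """Seeded shuffle-split of window indices into train/validation/test.

    Sizes follow a fixed rounding rule: train gets ``floor(p_train * n)``;
    the remainder is divided between validation (ceil of its proportional
    share) and test (the rest). With proportions (0.70, 0.15, 0.15) and
    n = 3941 this yields 2758/592/591.

    When ``config.patient_grouped_split`` is set, ``groups`` (one id per
    window) must be given and whole patients are assigned to one side only,
    approximating the same proportions at patient granularity.
    """
    if n_windows < 3:
        raise ValueError("need at least 3 windows to split")
    p_train, p_val, p_test = config.split_proportions
    if p_val + p_test <= 0 or p_train <= 0:
        raise ValueError("degenerate split proportions")
    rng = np.random.default_rng(config.seed)

    if config.patient_grouped_split:
        if groups is None:
            raise ValueError("patient_grouped_split requires groups")
        groups = np.asarray(groups)
        if len(groups) != n_windows:
            raise ValueError("groups length must equal n_windows")
        uniq = np.unique(groups)
        perm = rng.permutation(len(uniq))
        n_tr = int(np.floor(p_train * len(uniq)))
        rem = len(uniq) - n_tr
        n_va = int(np.ceil(rem * p_val / (p_val + p_test)))
        tr_ids = set(uniq[perm[:n_tr]])
        va_ids = set(uniq[perm[n_tr:n_tr + n_va]])
        idx = np.arange(n_windows)
        tr = idx[np.isin(groups, list(tr_ids))]
        va = idx[np.isin(groups, list(va_ids))]
        te = idx[~np.isin(groups, list(tr_ids | va_ids))]
        return DatasetSplit(train=tr, validation=va, test=te)

    perm = rng.permutation(n_windows)
    n_train = int(np.floor(p_train * n_windows))
    rem = n_windows - n_train
    n_val = int(np.ceil(rem * p_val / (p_val + p_test)))
    return DatasetSplit(
        train=perm[:n_train],
        validation=perm[n_train:n_train + n_val],
        test=perm[n_train + n_val:],
    )
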