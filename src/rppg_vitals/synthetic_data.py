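"""Synthetic facial-rPPG cohorts and session recordings.

Real facial videos from camera-based vital-sign studies are rarely shareable
(face data is identifiable), so every downstream stage of this package is
exercised on synthetic sessions whose *statistical structure* matches a
preoperative-clinic cohort: 200 patients, two 3-minute sessions each, RGB
traces from five facial regions of interest, with ground-truth systolic and
diastolic blood pressure (mm Hg) and hemoglobin concentration (g/dL).

The vital-to-waveform encoding is deliberately simple and invertible:

* systolic peak amplitude of the pulse waveform grows linearly with SBP,
* the diastolic exponential decay time constant grows linearly with DBP,
* the red/green pulsatile amplitude ratio grows linearly with hemoglobin,

so that parameter recovery by a regressor is a fair, checkable test. Monk
skin tone enters only as a baseline reflectance scaling plus a proportional
increase in sensor noise; no chromatic skin model is attempted.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ROI_NAMES",
    "PatientProfile",
    "CohortConfig",
    "SignalModelConfig",
    "SessionRecording",
    "sample_cohort",
    "synthesize_recording",
    "write_dataset",
    "read_dataset",
]

ROI_NAMES = ("forehead", "left_cheek", "right_cheek", "nose_and_cheeks", "full_face")

#: per-ROI baseline reflectance (R, G, B) for the lightest skin tone, trace units in [0, 1]
_ROI_BASELINES = {
    "forehead": (0.82, 0.62, 0.52),
    "left_cheek": (0.80, 0.60, 0.50),
    "right_cheek": (0.80, 0.60, 0.50),
    "nose_and_cheeks": (0.78, 0.58, 0.48),
    "full_face": (0.76, 0.56, 0.46),
}


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class PatientProfile:
    patient_id: str
    age: float
    sex: str  # "male" | "female"
    monk_tone: int  # 1..10, Monk Skin Tone scale
    comorbidities: frozenset  # subset of {"hypertension", "diabetes", "ischemic_heart_disease"}
    true_sbp: float  # mm Hg
    true_dbp: float  # mm Hg
    true_hb: float  # g/dL

    def __post_init__(self):
        if not 1 <= self.monk_tone <= 10:
            raise ConfigurationError(f"monk_tone {self.monk_tone} outside 1..10")
        if not (self.true_sbp > self.true_dbp > 0):
            raise ConfigurationError("requires true_sbp > true_dbp > 0")
        if self.true_hb <= 0:
            raise ConfigurationError("requires true_hb > 0")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level label distributions.

    Defaults reproduce the demographic structure of a 200-patient
    preoperative cohort: SBP mean 127.57 mm Hg on 84.5-191, DBP mean
    75.17 mm Hg on 54.5-98, hemoglobin 12.95 (SD 1.81) g/dL, 59% of
    patients with Monk skin tone 5-6. SBP/DBP are truncated normal with
    SD = (max - min)/6 (only mean and range are published for BP);
    hemoglobin is normal.
    """

    n_patients: int = 200
    sbp_mean: float = 127.57
    sbp_min: float = 84.5
    sbp_max: float = 191.0
    dbp_mean: float = 75.17
    dbp_min: float = 54.5
    dbp_max: float = 98.0
    hb_mean: float = 12.95
    hb_sd: float = 1.81
    tone56_fraction: float = 0.59
    age_mean: float = 58.23
    age_min: float = 21.0
    age_max: float = 84.0
    male_fraction: float = 0.38
    comorbidity_rates: tuple = (
        ("hypertension", 0.40),
        ("diabetes", 0.24),
        ("ischemic_heart_disease", 0.03),
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        for name, lo, mu, hi in (
            ("sbp", self.sbp_min, self.sbp_mean, self.sbp_max),
            ("dbp", self.dbp_min, self.dbp_mean, self.dbp_max),
        ):
            if not (lo <= mu <= hi):
                raise ConfigurationError(f"{name}: need min <= mean <= max, got {lo}, {mu}, {hi}")
        if not 0.0 <= self.tone56_fraction <= 1.0:
            raise ConfigurationError("tone56_fraction must be in [0, 1]")
        if self.hb_sd < 0:
            raise ConfigurationError("hb_sd must be >= 0")


@dataclass(frozen=True)
class SignalModelConfig:
    """Controls of the synthetic signal-to-vital encoding.

    ``sbp_amplitude_gain`` sets how strongly the systolic peak amplitude
    scales with SBP over its configured range, ``dbp_decay_gain`` how the
    diastolic decay time constant scales with DBP, and ``hb_ratio_gain``
    how the red/green pulsatile amplitude ratio scales with hemoglobin.
    ``tone_attenuation`` is the total baseline reflectance loss from Monk
    tone 1 to 10. ``noise_sd`` is additive Gaussian noise in trace units
    (the [0, 1] RGB scale); it grows by up to 50% across the tone scale.
    """

    frame_rate: float = 30.0  # Hz
    duration: float = 180.0  # seconds
    heart_rate_range: tuple = (55.0, 95.0)  # bpm
    sbp_amplitude_gain: float = 1.5
    dbp_decay_gain: float = 1.0
    hb_ratio_gain: float = 0.8
    tone_attenuation: float = 0.6
    noise_sd: float = 0.002
    offcenter_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.frame_rate <= 0 or self.duration <= 0:
            raise ConfigurationError("frame_rate and duration must be positive")
        if not 0.0 <= self.offcenter_fraction < 1.0:
            raise ConfigurationError("offcenter_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0.0 <= self.tone_attenuation < 1.0:
            raise ConfigurationError("tone_attenuation must be in [0, 1)")
        lo, hi = self.heart_rate_range
        if not 0 < lo <= hi:
            raise ConfigurationError("heart_rate_range must be positive and ordered")
        for g in (self.sbp_amplitude_gain, self.dbp_decay_gain, self.hb_ratio_gain):
            if not np.isfinite(g):
                raise ConfigurationError("gains must be finite")


@dataclass
class SessionRecording:
    """One patient session: per-ROI RGB traces plus per-frame centering flags."""

    patient_id: str
    session_index: int  # 1 or 2
    frame_rate: float
    duration: float
    roi_traces: dict  # ROI name -> (n_frames, 3) float array in [0, 1]
    centered: np.ndarray  # (n_frames,) bool
    heart_rate: float = float("nan")  # bpm; generator metadata

    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate * self.duration))


def _session_rng(seed: int, patient_id: str, session_index: int) -> np.random.Generator:
    # stable across runs: patient id folded in via CRC32
    return np.random.default_rng([seed, zlib.crc32(patient_id.encode()), session_index])


def sample_cohort(config: CohortConfig) -> list:
    """Draw a cohort of :class:`PatientProfile` deterministically from ``config.seed``.

    SBP and DBP come from truncated normals on their configured ranges,
    hemoglobin from a normal; per patient, DBP is redrawn until it is
    strictly below SBP. Monk tone is 5 or 6 with probability
    ``tone56_fraction``, otherwise uniform on 1-4 (the cohort structure
    being emulated contains no tones above 6).
    """
    from scipy.stats import truncnorm

    rng = np.random.default_rng(config.seed)

    def _trunc(mean, lo, hi, size, rng):
        if hi == lo:
            return np.full(size, float(mean))
        sd = (hi - lo) / 6.0
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)

    n = config.n_patients
    sbp = _trunc(config.sbp_mean, config.sbp_min, config.sbp_max, n, rng)
    dbp = _trunc(config.dbp_mean, config.dbp_min, config.dbp_max, n, rng)
    for i in range(n):  # enforce dbp < sbp by redraw
        while dbp[i] >= sbp[i]:
            dbp[i] = _trunc(config.dbp_mean, config.dbp_min, config.dbp_max, 1, rng)[0]
    hb = rng.normal(config.hb_mean, config.hb_sd, size=n)
    hb = np.abs(hb)  # keep strictly positive; reflection is negligible at 12.95 +/- 1.81
    age = _trunc(config.age_mean, config.age_min, config.age_max, n, rng)
    is56 = rng.random(n) < config.tone56_fraction
    tone = np.where(is56, rng.integers(5, 7, size=n), rng.integers(1, 5, size=n))
    sex = np.where(rng.random(n) < config.male_fraction, "male", "female")

    profiles = []
    for i in range(n):
        flags = frozenset(
            name for name, rate in config.comorbidity_rates if rng.random() < rate
        )
        profiles.append(
            PatientProfile(
                patient_id=f"P{i:04d}",
                age=float(age[i]),
                sex=str(sex[i]),
                monk_tone=int(tone[i]),
                comorbidities=flags,
                true_sbp=float(sbp[i]),
                true_dbp=float(dbp[i]),
                true_hb=float(hb[i]),
            )
        )
    return profiles


def _pulse_waveform(phase: np.ndarray, decay_tau: float) -> np.ndarray:
    """Unit-amplitude pulse template on beat phase in [0, 1).

    A Gaussian systolic peak followed by an exponential diastolic tail whose
    time constant ``decay_tau`` (in beat fractions) encodes DBP. The peak is
    wide enough (sigma 0.1 of the beat) that the fundamental heart-rate
    component dominates the spectrum, as in real photoplethysmograms.
    """
    peak = np.exp(-0.5 * ((phase - 0.2) / 0.1) ** 2)
    tail_phase = phase - 0.4
    tail = np.where(tail_phase > 0, 0.5 * np.exp(-tail_phase / decay_tau), 0.0)
    return peak + tail


def pulse_amplitude(true_sbp: float, config: SignalModelConfig) -> float:
    """Green-channel systolic amplitude: linear in SBP over its physiological range."""
    rel = (true_sbp - 84.5) / (191.0 - 84.5)
    return 0.01 * (1.0 + config.sbp_amplitude_gain * rel)


def decay_time_constant(true_dbp: float, config: SignalModelConfig) -> float:
    """Diastolic decay time constant in beat fractions: linear in DBP."""
    rel = (true_dbp - 54.5) / (98.0 - 54.5)
    return 0.08 + 0.15 * config.dbp_decay_gain * rel


def red_green_ratio(true_hb: float, config: SignalModelConfig) -> float:
    """Red/green pulsatile amplitude ratio: linear in hemoglobin."""
    return 0.5 + config.hb_ratio_gain * (true_hb - 8.0) / 10.0


def tone_baseline_factor(monk_tone: int, config: SignalModelConfig) -> float:
    """Baseline reflectance multiplier, 1 at tone 1 down to 1 - tone_attenuation at tone 10."""
    return 1.0 - config.tone_attenuation * (monk_tone - 1) / 9.0


def synthesize_recording(
    profile: PatientProfile,
    signal_config: SignalModelConfig,
    session_index: int = 1,
) -> SessionRecording:
    """Render one session's per-ROI RGB traces for a patient.

    Deterministic given ``(signal_config.seed, profile.patient_id,
    session_index)``. Heart rate is drawn once per patient (shared across
    sessions); phase and noise are per-session.
    """
    cfg = signal_config
    n_frames = int(round(cfg.frame_rate * cfg.duration))
    t = np.arange(n_frames) / cfg.frame_rate

    hr_rng = _session_rng(cfg.seed, profile.patient_id, 0)
    lo, hi = cfg.heart_rate_range
    heart_rate = float(hr_rng.uniform(lo, hi))

    rng = _session_rng(cfg.seed, profile.patient_id, session_index)
    phase0 = rng.uniform(0.0, 1.0)
    phase = (heart_rate / 60.0 * t + phase0) % 1.0

    tau = decay_time_constant(profile.true_dbp, cfg)
    wave = _pulse_waveform(phase, tau)

    amp_g = pulse_amplitude(profile.true_sbp, cfg)
    amp = np.array([red_green_ratio(profile.true_hb, cfg) * amp_g, amp_g, 0.3 * amp_g])

    tone_factor = tone_baseline_factor(profile.monk_tone, cfg)
    noise_sd = cfg.noise_sd * (1.0 + 0.5 * (profile.monk_tone - 1) / 9.0)

    roi_traces = {}
    for roi in ROI_NAMES:
        base = np.asarray(_ROI_BASELINES[roi]) * tone_factor
        trace = base[None, :] + wave[:, None] * amp[None, :]
        if noise_sd > 0:
            trace = trace + rng.normal(0.0, noise_sd, size=trace.shape)
        roi_traces[roi] = np.clip(trace, 0.0, 1.0)

    centered = rng.random(n_frames) >= cfg.offcenter_fraction

    return SessionRecording(
        patient_id=profile.patient_id,
        session_index=session_index,
        frame_rate=cfg.frame_rate,
        duration=cfg.duration,
        roi_traces=roi_traces,
        centered=centered,
        heart_rate=heart_rate,
    )


def _labels_frame(cohort: list) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in cohort],
            "sbp": [p.true_sbp for p in cohort],
            "dbp": [p.true_dbp for p in cohort],
            "hb": [p.true_hb for p in cohort],
            "age": [p.age for p in cohort],
            "sex": [p.sex for p in cohort],
            "monk_tone": [p.monk_tone for p in cohort],
            "comorbidities": ["|".join(sorted(p.comorbidities)) for p in cohort],
        }
    )


def write_dataset(cohort, recordings, path, configs=None) -> dict:
    """Write traces + labels CSVs and a JSON manifest under ``path``.

    Traces go to ``traces.csv`` in long format (patient_id, session, roi,
    frame, R, G, B, centered), labels to ``labels.csv``; the manifest
    records configs and seeds so a run can be reproduced. Round-trips
    losslessly through :func:`read_dataset`.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    label_ids = {p.patient_id for p in cohort}
    rec_ids = {r.patient_id for r in recordings}
    if not rec_ids <= label_ids:
        raise ValueError(f"recordings reference unknown patients: {sorted(rec_ids - label_ids)}")

    chunks = []
    for rec in recordings:
        n = rec.n_frames
        for roi in ROI_NAMES:
            tr = rec.roi_traces[roi]
            chunks.append(
                pd.DataFrame(
                    {
                        "patient_id": rec.patient_id,
                        "session": rec.session_index,
                        "roi": roi,
                        "frame": np.arange(n),
                        "R": tr[:, 0],
                        "G": tr[:, 1],
                        "B": tr[:, 2],
                        "centered": rec.centered.astype(int),
                        "frame_rate": rec.frame_rate,
                        "heart_rate": rec.heart_rate,
                    }
                )
            )
    traces = pd.concat(chunks, ignore_index=True) if chunks else pd.DataFrame(
        columns=["patient_id", "session", "roi", "frame", "R", "G", "B", "centered",
                 "frame_rate", "heart_rate"]
    )
    traces.to_csv(path / "traces.csv", index=False, float_format="%.17g")
    _labels_frame(cohort).to_csv(path / "labels.csv", index=False, float_format="%.17g")

    manifest = {
        "n_patients": len(cohort),
        "n_recordings": len(recordings),
        "files": {"traces": "traces.csv", "labels": "labels.csv"},
        "configs": {},
    }
    if configs:
        for name, cfg in configs.items():
            manifest["configs"][name] = dataclasses.asdict(cfg)
            if hasattr(cfg, "seed"):
                manifest.setdefault("seeds", {})[name] = cfg.seed
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def read_dataset(path):
    """Read back ``write_dataset`` output -> (labels DataFrame, list of SessionRecording)."""
    path = Path(path)
    labels = pd.read_csv(path / "labels.csv", float_precision="round_trip")
    traces = pd.read_csv(path / "traces.csv", float_precision="round_trip")
    recordings = []
    for (pid, sess), grp in traces.groupby(["patient_id", "session"], sort=True):
        frame_rate = float(grp["frame_rate"].iloc[0])
        roi_traces = {}
        centered = None
        for roi, sub in grp.groupby("roi"):
            sub = sub.sort_values("frame")
            roi_traces[roi] = sub[["R", "G", "B"]].to_numpy()
            centered = sub["centered"].to_numpy().astype(bool)
        n = len(centered)
        recordings.append(
            SessionRecording(
                patient_id=str(pid),
                session_index=int(sess),
                frame_rate=frame_rate,
                duration=n / frame_rate,
                roi_traces=roi_traces,
                centered=centered,
                heart_rate=float(grp["heart_rate"].iloc[0]),
            )
        )
    return labels, recordings
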