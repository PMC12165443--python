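"""End-to-end orchestration: generate -> preprocess -> train -> predict -> validate.

One seeded run produces a manifest with per-stage row counts (how many
windows were generated, survived quality filtering and extreme-label
exclusion, and how the remainder was split) plus per-vital agreement and
ISO 81060-2 reports on the held-out test windows. Stage seeds are derived
deterministically from the global seed, so any stage can be re-run in
isolation with identical randomness.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import lds_regression as ldr
from . import preprocess as pp
from . import synthetic_data as sd
from . import validation_stats as vs

__all__ = ["RunConfig", "RunManifest", "stage_seed", "run_pipeline", "report"]

_BP_TARGETS = ("sbp", "dbp")


def stage_seed(global_seed: int, stage_name: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (global_seed * 2654435761 + zlib.crc32(stage_name.encode())) % (2 ** 31)


def _default_lds():
    return {
        "sbp": ldr.LDSConfig(bin_width=1.0),
        "dbp": ldr.LDSConfig(bin_width=1.0),
        "hb": ldr.LDSConfig(bin_width=0.1),
    }


def _default_regressors():
    return {t: ldr.RegressorConfig(target=t) for t in ("sbp", "dbp", "hb")}


@dataclass
class RunConfig:
    cohort: sd.CohortConfig = field(default_factory=sd.CohortConfig)
    signal: sd.SignalModelConfig = field(default_factory=sd.SignalModelConfig)
    preprocess: pp.PreprocessConfig = field(default_factory=pp.PreprocessConfig)
    lds: dict = field(default_factory=_default_lds)
    regressors: dict = field(default_factory=_default_regressors)
    targets: tuple = ("sbp", "dbp", "hb")
    sessions_per_patient: int = 2
    output_dir: str | Path = "run_output"
    write_traces: bool = False  # the long-format trace CSV is large; opt in
    global_seed: int = 0

    def __post_init__(self):
        unknown = set(self.targets) - {"sbp", "dbp", "hb"}
        if unknown:
            raise ValueError(f"unknown targets: {sorted(unknown)}")
        for t in self.targets:
            if t not in self.lds or t not in self.regressors:
                raise ValueError(f"missing lds/regressor config for target {t!r}")


@dataclass
class RunManifest:
    config: dict
    stage_seeds: dict
    n_patients: int
    n_recordings: int
    n_windows_generated: int
    n_windows_quality: int
    n_windows_retained: int
    split_sizes: tuple
    model_parameters: dict
    agreement: dict  # target -> AgreementReport fields
    iso: dict  # target -> ISOValidationReport fields (BP targets only)
    wilcoxon: dict  # target -> (statistic, p)
    shapiro: dict  # target -> (W, p) on test differences
    artifacts: dict

    def validate_accounting(self) -> None:
        ok = (self.n_windows_generated >= self.n_windows_quality >= self.n_windows_retained
              and sum(self.split_sizes) == self.n_windows_retained)
        if not ok:
            raise AssertionError("manifest row counts are inconsistent")


def _derive_configs(config: RunConfig) -> RunConfig:
    """Rewrite sub-config seeds from the global seed."""
    return dataclasses.replace(
        config,
        cohort=dataclasses.replace(config.cohort, seed=stage_seed(config.global_seed, "cohort")),
        signal=dataclasses.replace(config.signal, seed=stage_seed(config.global_seed, "signal")),
        preprocess=dataclasses.replace(
            config.preprocess, seed=stage_seed(config.global_seed, "split")),
        regressors={
            t: dataclasses.replace(r, seed=stage_seed(config.global_seed, f"train_{t}"))
            for t, r in config.regressors.items()
        },
    )


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages in order and write ``manifest.json`` last."""
    config = _derive_configs(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "generate"
    try:
        cohort = sd.sample_cohort(config.cohort)
        recordings = []
        for p in cohort:
            for s in range(1, config.sessions_per_patient + 1):
                recordings.append(sd.synthesize_recording(p, config.signal, s))
        if config.write_traces:
            sd.write_dataset(cohort, recordings, out / "dataset",
                             configs={"cohort": config.cohort, "signal": config.signal})
        else:
            sd._labels_frame(cohort).to_csv(out / "labels.csv", index=False)

        stage = "preprocess"
        by_id = {p.patient_id: p for p in cohort}
        windows = []
        for rec in recordings:
            prof = by_id[rec.patient_id]
            labels = pp.VitalLabels(sbp=prof.true_sbp, dbp=prof.true_dbp, hb=prof.true_hb)
            windows.extend(pp.segment_windows(rec, config.preprocess, labels))
        n_generated = len(windows)
        windows = pp.quality_filter(windows, config.preprocess)
        n_quality = len(windows)
        windows = pp.exclude_extremes(windows, config.preprocess)
        n_retained = len(windows)
        groups = [w.patient_id for w in windows] if config.preprocess.patient_grouped_split else None
        split = pp.split_dataset(n_retained, config.preprocess, groups=groups)
        tr = [windows[i] for i in split.train]
        va = [windows[i] for i in split.validation]
        te = [windows[i] for i in split.test]

        stage = "train"
        models, history_rows = {}, []
        for t in config.targets:
            rcfg = config.regressors[t]
            y_tr = np.array([getattr(w.labels, t) for w in tr])
            weights = ldr.lds_weights(y_tr, config.lds[t])
            net = ldr.build_regressor(rcfg, input_length=tr[0].centered.shape[0])
            models[t] = ldr.train(net, tr, va, weights, rcfg)
            for h in models[t].training_history:
                history_rows.append({"target": t, **h})
        pd.DataFrame(history_rows).to_csv(out / "training_history.csv", index=False)

        stage = "predict"
        pred_rows = []
        pairs = {}
        for t in config.targets:
            yhat = ldr.predict(models[t], te)
            ytrue = np.array([getattr(w.labels, t) for w in te])
            ids = np.array([w.patient_id for w in te])
            pairs[t] = vs.PairedReadings(subject_id=ids, predicted=yhat, reference=ytrue)
            for w, ph, rv in zip(te, yhat, ytrue):
                pred_rows.append({"patient_id": w.patient_id, "session": w.session_index,
                                  "window": w.window_index, "target": t,
                                  "predicted": ph, "reference": rv})
        pd.DataFrame(pred_rows).to_csv(out / "predictions.csv", index=False)

        stage = "validate"
        agreement, iso, wilcox, shapiro = {}, {}, {}, {}
        for t in config.targets:
            rep = vs.agreement_report(pairs[t])
            agreement[t] = dataclasses.asdict(rep)
            vs.bland_altman(pairs[t], plot_path=out / f"bland_altman_{t}.png")
            d = pairs[t].differences
            if 3 <= len(d) <= 5000 and np.ptp(d) > 0:
                shapiro[t] = vs.normality_test(d)
            wilcox[t] = vs.wilcoxon_signed_rank(pairs[t])
            if t in _BP_TARGETS:
                iso[t] = dataclasses.asdict(vs.iso_validation_report(pairs[t]))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = RunManifest(
        config={
            "cohort": dataclasses.asdict(config.cohort),
            "signal": dataclasses.asdict(config.signal),
            "preprocess": dataclasses.asdict(config.preprocess),
            "lds": {t: dataclasses.asdict(c) for t, c in config.lds.items()},
            "regressors": {t: dataclasses.asdict(c) for t, c in config.regressors.items()},
            "targets": list(config.targets),
            "global_seed": config.global_seed,
        },
        stage_seeds={s: stage_seed(config.global_seed, s)
                     for s in ("cohort", "signal", "split")},
        n_patients=len(cohort),
        n_recordings=len(recordings),
        n_windows_generated=n_generated,
        n_windows_quality=n_quality,
        n_windows_retained=n_retained,
        split_sizes=split.sizes(),
        model_parameters={t: models[t].n_parameters for t in config.targets},
        agreement=agreement,
        iso=iso,
        wilcoxon={t: list(v) for t, v in wilcox.items()},
        shapiro={t: list(v) for t, v in shapiro.items()},
        artifacts={"predictions": "predictions.csv",
                   "training_history": "training_history.csv",
                   "labels": "labels.csv" if not config.write_traces else "dataset/labels.csv"},
    )
    manifest.validate_accounting()
    (out / "manifest.json").write_text(
        json.dumps(dataclasses.asdict(manifest), indent=2, default=_json_default))
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray, tuple, set, frozenset)):
        return list(obj)
    return str(obj)


_UNITS = {"sbp": "mm Hg", "dbp": "mm Hg", "hb": "g/dL"}


def _fmt(x, nd=2):
    return f"{x:.{nd}f}"


def report(manifest: RunManifest) -> str:
    """Render a manifest as markdown tables (agreement and ISO summaries)."""
    if isinstance(manifest, dict):
        required = {"agreement", "iso", "split_sizes", "n_windows_retained"}
        missing = required - set(manifest)
        if missing:
            raise ValueError(f"incomplete manifest, missing: {sorted(missing)}")
        agreement, iso = manifest["agreement"], manifest["iso"]
        split_sizes = manifest["split_sizes"]
        wilcox = manifest.get("wilcoxon", {})
    else:
        agreement, iso = manifest.agreement, manifest.iso
        split_sizes = manifest.split_sizes
        wilcox = manifest.wilcoxon

    lines = []
    lines.append("## Dataset")
    lines.append(f"Train/validation/test windows: {tuple(split_sizes)}")
    lines.append("")
    lines.append("## Agreement (test set)")
    lines.append("| Metric | " + " | ".join(t.upper() for t in agreement) + " |")
    lines.append("|---" * (len(agreement) + 1) + "|")
    rows = [
        ("Mean absolute percentage error (%)", lambda a: _fmt(a["mape"])),
        ("Reference, mean (SD)", lambda a: f"{_fmt(a['mean_ref'])} ({_fmt(a['sd_ref'])})"),
        ("Predicted, mean (SD)", lambda a: f"{_fmt(a['mean_pred'])} ({_fmt(a['sd_pred'])})"),
        ("Mean difference (SD)", lambda a: f"{_fmt(a['mean_diff'])} ({_fmt(a['sd_diff'])})"),
        ("95% CI half-width", lambda a: f"±{_fmt(a['ci95_halfwidth'])}"),
        ("Bland-Altman LoA", lambda a: f"{_fmt(a['ba_loa_low'])} to {_fmt(a['ba_loa_high'])}"),
        ("n", lambda a: str(a["n"])),
    ]
    for name, fn in rows:
        lines.append(f"| {name} | " + " | ".join(fn(a) for a in agreement.values()) + " |")
    lines.append("")
    lines.append("## ISO 81060-2 criteria")
    lines.append("| Criterion | Limit (mm Hg) | Estimate (SD) | Fulfills |")
    lines.append("|---|---|---|---|")
    for t in ("sbp", "dbp"):
        if t not in iso:
            lines.append(f"| Criterion 1 ({t.upper()}) | <8 | not computed | — |")
            lines.append(f"| Criterion 2 ({t.upper()}) | — | not computed | — |")
            continue
        r = iso[t]
        lines.append(
            f"| Criterion 1 ({t.upper()}) | <8 | {_fmt(r['c1_mean'])} ({_fmt(r['c1_sd'])}) "
            f"| {'Yes' if r['c1_pass'] else 'No'} |")
        lines.append(
            f"| Criterion 2 ({t.upper()}) | <{_fmt(r['c2_sd_max'])} "
            f"| {_fmt(r['c2_mean'])} ({_fmt(r['c2_sd'])}) "
            f"| {'Yes' if r['c2_pass'] else 'No'} |")
    if wilcox:
        lines.append("")
        lines.append("## Wilcoxon signed-rank (predicted vs reference)")
        lines.append("| Target | statistic | p |")
        lines.append("|---|---|---|")
        for t, (s, p) in wilcox.items():
            lines.append(f"| {t.upper()} | {_fmt(s)} | {p:.3g} |")
    return "\n".join(lines) + "\n"
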