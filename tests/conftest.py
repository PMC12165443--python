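import numpy as np
import pytest

from rppg_vitals import lds_regression as ldr
from rppg_vitals import preprocess as pp
from rppg_vitals import synthetic_data as sd


def build_window_sets(
    n_patients=60,
    duration=60.0,
    noise_sd=0.001,
    seed=1,
    sbp_mean=127.57,
    offcenter_fraction=0.02,
):
    """Generate a cohort, render two sessions per patient, window, filter, split.

    Returns (train, validation, test) lists of MeasurementWindow.
    """
    cohort = sd.sample_cohort(
        sd.CohortConfig(n_patients=n_patients, sbp_mean=sbp_mean, seed=seed)
    )
    scfg = sd.SignalModelConfig(
        duration=duration,
        noise_sd=noise_sd,
        offcenter_fraction=offcenter_fraction,
        seed=seed + 1,
    )
    pcfg = pp.PreprocessConfig(seed=seed + 2)
    windows = []
    for p in cohort:
        labels = pp.VitalLabels(sbp=p.true_sbp, dbp=p.true_dbp, hb=p.true_hb)
        for s in (1, 2):
            rec = sd.synthesize_recording(p, scfg, s)
            windows.extend(pp.segment_windows(rec, pcfg, labels))
    windows = pp.quality_filter(windows, pcfg)
    windows = pp.exclude_extremes(windows, pcfg)
    split = pp.split_dataset(len(windows), pcfg)
    return (
        [windows[i] for i in split.train],
        [windows[i] for i in split.validation],
        [windows[i] for i in split.test],
    )


def train_and_score(train_w, val_w, test_w, target, epochs, seed, use_lds=True):
    """Train one vital-sign model and return (test MAPE %, predictions, truths)."""
    y_tr = np.array([getattr(w.labels, target) for w in train_w])
    bin_width = 0.1 if target == "hb" else 1.0
    if use_lds:
        weights = ldr.lds_weights(y_tr, ldr.LDSConfig(bin_width=bin_width))
    else:
        weights = np.ones(len(y_tr))
    rcfg = ldr.RegressorConfig(target=target, epochs=epochs, seed=seed)
    model = ldr.train(ldr.build_regressor(rcfg), train_w, val_w, weights, rcfg)
    yhat = ldr.predict(model, test_w)
    ytrue = np.array([getattr(w.labels, target) for w in test_w])
    mape = float(100.0 * np.mean(np.abs(yhat - ytrue) / ytrue))
    return mape, yhat, ytrue


@pytest.fixture(scope="session")
def window_factory():
    return build_window_sets


@pytest.fixture(scope="session")
def trainer():
    return train_and_score


@pytest.fixture(scope="session")
def small_windows():
    """A small filtered/split window set shared across fast tests."""
    return build_window_sets(n_patients=10, duration=30.0, noise_sd=0.002, seed=3)
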