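import pytest

from smfskit import SimulationConfig, simulate_curve, simulate_ensemble
from smfskit.correct import correct_baseline, correct_invols, smooth_median


def preprocess(curve):
    """Standard correction chain; returns (unsmoothed, smoothed) curves."""
    pre = correct_baseline(
        correct_invols(curve, 1.0, float(curve.metadata.get("invols", 1.0))))
    return pre, smooth_median(pre)


@pytest.fixture(scope="session")
def clean_curve():
    """One noise-free, drift-free default-construct curve with ground truth."""
    cfg = SimulationConfig(noise_sd=0.0, baseline_drift_rate=0.0, seed=42)
    return simulate_curve(cfg)


@pytest.fixture(scope="session")
def clean_ensemble():
    """40 noise-free curves for detector/loading-rate agreement tests."""
    cfg = SimulationConfig(noise_sd=0.0, baseline_drift_rate=0.0)
    return simulate_ensemble(cfg, 40, seed=3)


@pytest.fixture(scope="session")
def noisy_ensemble():
    """150 curves at default noise/drift for sensitivity and filter tests."""
    return simulate_ensemble(SimulationConfig(), 150, seed=7)
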