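"""Event detection, contour-length increments, fingerprint classification."""

import math

import numpy as np
import pytest

from smfskit.bellevans import BellEvansParams
from smfskit.events import (
    UnfoldingEvent,
    analyze_curve,
    classify_fingerprint,
    detect_ruptures,
    loading_rate_at_rupture,
    write_event_table,
)
from smfskit.simulate import ForceCurve, SegmentSpec, SimulationConfig, simulate_ensemble
from tests.conftest import preprocess


def _match(det_events, truth, tol=20):
    """Greedy index-matching of detected events to ground truth."""
    used = set()
    pairs = []
    for g in truth.events:
        for k, d in enumerate(det_events):
            if k not in used and abs(d.index - g.index) <= tol:
                used.add(k)
                pairs.append((d, g))
                break
    return pairs, len(det_events) - len(used)


def test_noise_free_sawtooth_detected_exactly(clean_curve):
    curve, truth = clean_curve
    pre, smoothed = preprocess(curve)
    events = detect_ruptures(smoothed, raw_curve=pre)
    assert len(events) == len(truth.events)
    pairs, spurious = _match(events, truth)
    assert spurious == 0
    for det, true in pairs:
        # the rupture falls inside one sampling interval, so the read-out
        # can sit up to one interval's force rise below the true value
        step_rise = true.loading_rate * (curve.time[1] - curve.time[0])
        assert det.rupture_force == pytest.approx(true.rupture_force,
                                                  abs=1.5 + step_rise)


def test_flat_curve_yields_no_events():
    n = 500
    flat = ForceCurve(np.arange(n) * 1e-4, np.linspace(0, 50, n),
                      np.zeros(n), {"spring_constant": 143.0})
    assert detect_ruptures(flat) == []


def test_noise_free_increments_recover_34_and_45(clean_ensemble):
    fp_sums, coh = [], []
    for curve, _truth in clean_ensemble:
        pre, smoothed = preprocess(curve)
        ana = analyze_curve(smoothed, raw=pre)
        if ana.classification.accepted:
            fp_sums.append(sum(ev.increment
                               for ev in ana.classification.fingerprint_events))
            coh.append(ana.classification.cohesin_event.increment)
    assert len(fp_sums) >= 30
    assert np.median(fp_sums) == pytest.approx(34.0, abs=0.5)
    assert np.median(coh) == pytest.approx(45.0, abs=0.5)


def test_noisy_ensemble_sensitivity_and_precision(noisy_ensemble):
    recovered = total = spurious = 0
    for curve, truth in noisy_ensemble:
        pre, smoothed = preprocess(curve)
        events = detect_ruptures(smoothed, raw_curve=pre)
        pairs, extra = _match(events, truth)
        recovered += len(pairs)
        total += len(truth.events)
        spurious += extra
    assert recovered / total >= 0.95
    assert spurious / total <= 0.02


def test_loading_rates_match_ground_truth_noise_free(clean_ensemble):
    rel_errors = []
    for curve, truth in clean_ensemble[:20]:
        pre, smoothed = preprocess(curve)
        ana = analyze_curve(smoothed, raw=pre)
        for det, true in _match(ana.events, truth, tol=3)[0]:
            if math.isfinite(det.loading_rate):
                rel_errors.append(abs(det.loading_rate - true.loading_rate)
                                  / true.loading_rate)
    assert len(rel_errors) > 40
    assert np.percentile(rel_errors, 95) < 0.05


def test_loading_rate_of_linear_ramp_is_exact_slope():
    """Linear force ramp: the fitted loading rate equals the analytic dF/dt.
    With deflection = (alpha*v*t), the force is k*alpha*v*t, so the slope
    must be exactly k*alpha*v."""
    k, v, alpha, dt = 143.0, 1600.0, 0.01, 1e-4
    n = 400
    t = np.arange(n) * dt
    deflection = alpha * v * t  # nm
    curve = ForceCurve(t, v * t, deflection, {"spring_constant": k})
    ev = UnfoldingEvent(index=n - 1, rupture_force=float(curve.force[-1]))
    rate = loading_rate_at_rupture(curve, ev, window=3.0)
    assert rate == pytest.approx(k * alpha * v, rel=1e-9)


def test_loading_rate_increases_with_pulling_speed():
    med = []
    for speed in (400.0, 1600.0):
        ens = simulate_ensemble(
            SimulationConfig(noise_sd=0.0, baseline_drift_rate=0.0,
                             pulling_speed=speed), 25, seed=6)
        rates = []
        for curve, _t in ens:
            pre, smoothed = preprocess(curve)
            ana = analyze_curve(smoothed, raw=pre)
            if ana.classification.accepted:
                rates.append(ana.classification.cohesin_event.loading_rate)
        med.append(np.median(rates))
    assert med[1] > med[0]


def _ev(inc, final=False):
    e = UnfoldingEvent(index=0, rupture_force=100.0)
    e.increment = inc
    e.final = final
    return e


class TestClassification:
    def test_canonical_pattern_accepted(self):
        events = [_ev(15.0), _ev(19.0), _ev(45.0), _ev(math.nan, final=True)]
        cls = classify_fingerprint(events)
        assert cls.accepted and cls.reason == "ok"
        assert len(cls.fingerprint_events) == 2
        assert cls.cohesin_event.increment == 45.0

    def test_merged_fingerprint_accepted(self):
        events = [_ev(34.0), _ev(45.0), _ev(math.nan, final=True)]
        cls = classify_fingerprint(events)
        assert cls.accepted
        assert len(cls.fingerprint_events) == 1

    def test_missing_fingerprint_rejected(self):
        events = [_ev(45.0), _ev(math.nan, final=True)]
        assert classify_fingerprint(events).reason == "no_ddFLN4_pattern"

    def test_double_tether_rejected_as_extra_events(self):
        events = [_ev(15.0), _ev(19.0), _ev(45.0), _ev(45.0),
                  _ev(math.nan, final=True)]
        assert classify_fingerprint(events).reason == "extra_events"

    def test_missing_final_rupture_rejected(self):
        events = [_ev(15.0), _ev(19.0), _ev(45.0)]
        assert classify_fingerprint(events).reason == "no_final_rupture"

    def test_missing_cohesin_rejected(self):
        events = [_ev(15.0), _ev(19.0), _ev(math.nan, final=True)]
        assert classify_fingerprint(events).reason == "no_cohesin_increment"


def test_contaminated_ensemble_filtered(noisy_ensemble):
    """30% contaminated curves (double-cohesin tether or missing
    fingerprint): clean traces pass, contaminated ones are rejected."""
    kin = BellEvansParams(0.34, 1.3e-2)
    double = SimulationConfig(segments=(
        SegmentSpec("linker", 35.0),
        SegmentSpec("ddFLN4", 4.0, 34.0, BellEvansParams(0.45, 0.35), (15.0, 19.0)),
        SegmentSpec("cohesin", 4.0, 45.0, kin),
        SegmentSpec("cohesin2", 4.0, 45.0, kin)))
    no_fp = SimulationConfig(segments=(
        SegmentSpec("linker", 39.0),
        SegmentSpec("cohesin", 4.0, 45.0, kin)))

    def accepted(ens):
        out = []
        for curve, _t in ens:
            pre, smoothed = preprocess(curve)
            out.append(analyze_curve(smoothed, raw=pre).classification.accepted)
        return np.asarray(out)

    clean = accepted(noisy_ensemble)
    contaminated = np.concatenate([accepted(simulate_ensemble(double, 30, 14)),
                                   accepted(simulate_ensemble(no_fp, 30, 15))])
    assert clean.mean() >= 0.95
    assert (~contaminated).mean() >= 0.90


def test_event_table_written(tmp_path, clean_curve):
    curve, _truth = clean_curve
    pre, smoothed = preprocess(curve)
    ana = analyze_curve(smoothed, raw=pre)
    path = tmp_path / "events.tsv"
    write_event_table({"c0": ana}, path)
    lines = path.read_text().strip().splitlines()
    assert lines[0].startswith("curve_id\t")
    assert len(lines) == 1 + len(ana.events)
    assert any("\tcohesin\t" in ln for ln in lines)
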