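"""Trajectory simulator: physics, ground truth, determinism, file I/O."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import ks_2samp

from smfskit.bellevans import BellEvansParams, most_probable_force, sample_rupture_forces
from smfskit.simulate import (
    SegmentSpec,
    SimulationConfig,
    fingerprint_construct,
    read_curve,
    simulate_curve,
    simulate_ensemble,
    write_curve,
    write_ground_truth,
    write_manifest,
)
from smfskit.wlc import wlc_extension, wlc_force, wlc_stiffness


def test_segment_substeps_must_sum_to_increment():
    with pytest.raises(ValueError, match="sum"):
        SegmentSpec("bad", 4.0, contour_length_increment=34.0,
                    kinetics=BellEvansParams(0.4, 0.1),
                    substep_increments=(15.0, 18.0))
    seg = SegmentSpec("ok", 4.0, contour_length_increment=34.0,
                      kinetics=BellEvansParams(0.4, 0.1),
                      substep_increments=(15.0, 19.0))
    assert seg.steps == (15.0, 19.0)


def test_identical_config_gives_bit_identical_output():
    cfg = SimulationConfig(seed=77)
    c1, g1 = simulate_curve(cfg)
    c2, g2 = simulate_curve(cfg)
    np.testing.assert_array_equal(c1.deflection, c2.deflection)
    np.testing.assert_array_equal(c1.time, c2.time)
    assert g1 == g2


def test_never_unfolding_segment_follows_analytic_series_curve():
    """Zero noise, one inert segment: the recorded force must equal the
    analytic solution of the cantilever+WLC force balance at every sample."""
    lc = 60.0
    cfg = SimulationConfig(segments=(SegmentSpec("inert", lc),),
                           handle_rupture=BellEvansParams(0.13, 1e-12),  # never fires
                           noise_sd=0.0, baseline_drift_rate=0.0, seed=1,
                           max_force=800.0)
    curve, truth = simulate_curve(cfg)
    assert truth.events == ()
    k = cfg.spring_constant
    for i in range(10, curve.time.size, 97):
        D = curve.piezo_position[i]

        def balance(dd, D=D):
            x = min(max(D - dd, 0.0), lc * (1 - 1e-12))
            return k * dd - wlc_force(x, lc)

        d = brentq(balance, max(0.0, D - lc * (1 - 1e-9)), D + 1e-9, xtol=1e-12)
        assert curve.force[i] == pytest.approx(k * d, abs=1e-6)


def test_ground_truth_increments_match_configuration(noisy_ensemble):
    for _curve, truth in noisy_ensemble[:50]:
        by_segment = {ev.segment: ev.increment for ev in truth.events}
        if "ddFLN4/1" in by_segment:
            assert by_segment["ddFLN4/1"] == 15.0
        if "ddFLN4/2" in by_segment:
            assert by_segment["ddFLN4/2"] == 19.0
        if "cohesin" in by_segment:
            assert by_segment["cohesin"] == 45.0
        indices = [ev.index for ev in truth.events]
        assert indices == sorted(indices)


def test_mean_rupture_force_increases_with_pulling_speed():
    means = []
    for speed in (400.0, 800.0, 1600.0, 3200.0):
        cfg = SimulationConfig(noise_sd=0.0, baseline_drift_rate=0.0,
                               pulling_speed=speed)
        ens = simulate_ensemble(cfg, 50, seed=4)
        forces = [ev.rupture_force for _c, g in ens for ev in g.events
                  if ev.segment == "cohesin"]
        means.append(np.mean(forces))
    assert all(b > a for a, b in zip(means, means[1:]))


def test_trajectory_ruptures_match_direct_sampler_by_ks():
    """Self-consistency of the hazard-integration simulator against exact
    inverse-CDF sampling: with a stiff chain the loading rate is nearly
    constant, and the analytic series-stiffness rate at the mode gives the
    reference distribution."""
    lc = 5.0
    kin = BellEvansParams(0.34, 1.3e-2)
    cfg = SimulationConfig(segments=(SegmentSpec("stiff", lc),),
                           handle_rupture=kin, noise_sd=0.0,
                           baseline_drift_rate=0.0, sampling_rate=1e5)
    ens = simulate_ensemble(cfg, 300, seed=11)
    forces = np.array([g.handle_rupture_force for _c, g in ens])

    def effective_rate(F):
        x = wlc_extension(F, lc)
        return cfg.pulling_speed / (1 / cfg.spring_constant + 1 / wlc_stiffness(x, lc))

    F_star = 150.0
    for _ in range(20):
        F_star = most_probable_force(kin, effective_rate(F_star))
    draws = sample_rupture_forces(kin, effective_rate(F_star), 300, seed=1)
    assert ks_2samp(forces, draws).pvalue > 0.01


def test_time_step_halving_converges():
    """Hazard integration is exact in the small-step limit: halving the step
    moves the mean cohesin rupture force by well under the distribution SD."""
    means = []
    for rate in (1e4, 2e4):
        cfg = SimulationConfig(noise_sd=0.0, baseline_drift_rate=0.0,
                               sampling_rate=rate)
        ens = simulate_ensemble(cfg, 150, seed=3)
        forces = [ev.rupture_force for _c, g in ens for ev in g.events
                  if ev.segment == "cohesin"]
        means.append(np.mean(forces))
    assert abs(means[1] - means[0]) < 2.0  # pN; distribution SD ~ 15 pN


def test_curve_file_round_trip(tmp_path, clean_curve):
    curve, truth = clean_curve
    path = tmp_path / "curve_0000.tsv"
    write_curve(curve, path)
    back = read_curve(path)
    np.testing.assert_allclose(back.time, curve.time, rtol=1e-8)
    np.testing.assert_allclose(back.deflection, curve.deflection, rtol=1e-6)
    assert back.metadata["spring_constant"] == curve.spring_constant
    write_ground_truth({"curve_0000": truth}, tmp_path / "gt.tsv")
    lines = (tmp_path / "gt.tsv").read_text().strip().splitlines()
    assert len(lines) == 1 + len(truth.events)
    write_manifest([{"id": "curve_0000", "file": "curve_0000.tsv"}],
                   tmp_path / "manifest.json")
    assert (tmp_path / "manifest.json").exists()


def test_default_construct_layout():
    segs = fingerprint_construct()
    names = [s.name for s in segs]
    assert names == ["linker", "ddFLN4", "cohesin"]
    dd = segs[1]
    assert sum(dd.substep_increments) == 34.0
    assert segs[2].contour_length_increment == 45.0
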