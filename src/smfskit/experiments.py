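"""Canned verification experiments: parameter recovery on synthetic data.

Because single-molecule rupture datasets are rarely deposited, the honest
verification of a force-spectroscopy analysis stack is parameter recovery:
generate rupture data from known Bell-Evans parameters, run the full
analysis, and compare the recovered parameters with the generating ones.
Two experiments are provided:

* :func:`dfs_recovery` — the dynamic-force-spectrum loop: sample rupture
  forces at several loading rates from the analytic rupture-force density,
  extract the per-rate most probable force by KDE, and fit the
  force-vs-log-rate relation.
* :func:`fingerprint_experiment` — the full curve-level loop: simulate
  noisy pulling curves, correct, detect ruptures, transform to
  contour-length space, filter by the 34 nm / 45 nm fingerprint, and
  report the measured increment medians and acceptance rate.

Reference parameter sets from dynamic force spectra of cohesin unfolding
(without/with dockerin bound) are included as module constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bellevans import BellEvansParams, sample_rupture_forces
from .correct import correct_baseline, correct_invols, smooth_median
from .events import analyze_curve
from .fitting import DFSFit, fit_dfs, kde_modes
from .simulate import SimulationConfig, simulate_ensemble

#: Published cohesin unfolding kinetics (dynamic force spectra, AFM
#: pulling speeds 400-3200 nm/s): (delta_x nm, k0 1/s).
COH1_APO = BellEvansParams(delta_x=0.34, k0=1.3e-2)
COH1_BOUND = BellEvansParams(delta_x=0.16, k0=8.6e-3)
COH5_APO = BellEvansParams(delta_x=0.16, k0=11.7e-6)
COH5_BOUND = BellEvansParams(delta_x=0.13, k0=9.1e-6)

#: Loading rates (pN/s) standing in for the four pulling speeds: log-spaced
#: over the decade range AFM experiments at 400-3200 nm/s cover.
DEFAULT_DFS_RATES: tuple[float, ...] = tuple(np.geomspace(1e3, 1e5, 4))


def dfs_recovery(params: BellEvansParams,
                 loading_rates=DEFAULT_DFS_RATES,
                 n_per_rate: int = 2000,
                 seed: int = 0) -> DFSFit:
    """Recover (delta_x, k0) from synthetic per-rate rupture-force samples.

    For each loading rate, ``n_per_rate`` forces are drawn by exact
    inverse-CDF sampling, the most probable force is taken as the KDE mode,
    and the force-vs-ln(rate) relation is fitted.  With correct statistics
    the fitted parameters match the generating ones up to sampling noise.
    """
    rng = np.random.default_rng(seed)
    points = []
    for rate in loading_rates:
        forces = sample_rupture_forces(params, rate, n_per_rate, rng)
        res = kde_modes(forces)
        mode = res.modes[int(np.argmax(res.densities))]
        points.append((float(rate), mode))
    return fit_dfs(points, kBT=params.kBT)


@dataclass
class FingerprintResult:
    n_curves: int
    n_accepted: int
    fingerprint_median_nm: float
    cohesin_median_nm: float
    fingerprint_increments: np.ndarray
    cohesin_increments: np.ndarray

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_curves


def fingerprint_experiment(n_curves: int = 500, seed: int = 0,
                           config: SimulationConfig | None = None) -> FingerprintResult:
    """Simulate, correct, detect and classify a curve ensemble; report the
    measured fingerprint (summed two-substep) and cohesin increments."""
    cfg = config if config is not None else SimulationConfig()
    fp_incs, coh_incs = [], []
    n_accepted = 0
    for curve, _truth in simulate_ensemble(cfg, n_curves, seed):
        pre = correct_baseline(
            correct_invols(curve, 1.0, float(curve.metadata.get("invols", 1.0))))
        smoothed = smooth_median(pre)
        ana = analyze_curve(smoothed, raw=pre)
        cls = ana.classification
        if cls.accepted:
            n_accepted += 1
            fp_incs.append(sum(ev.increment for ev in cls.fingerprint_events))
            coh_incs.append(cls.cohesin_event.increment)
    fp = np.asarray(fp_incs)
    coh = np.asarray(coh_incs)
    return FingerprintResult(
        n_curves=n_curves, n_accepted=n_accepted,
        fingerprint_median_nm=float(np.median(fp)) if fp.size else float("nan"),
        cohesin_median_nm=float(np.median(coh)) if coh.size else float("nan"),
        fingerprint_increments=fp, cohesin_increments=coh)
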