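"""Rupture-force statistics: histogram fits, KDE modes, dynamic force spectra.

Pooled rupture forces of one construct x condition x pulling speed are
summarized either by a least-squares fit of the Bell-Evans density to the
force histogram, or — for distributions that are not Bell-Evans shaped
(multi-barrier landscapes, fold mixtures) — by the modes of a Gaussian
kernel density estimate.  The most probable forces at several pulling
speeds, plotted against the logarithm of the most probable loading rate,
form the dynamic force spectrum, whose Bell-Evans fit yields the barrier
parameters dx (distance to transition state) and k0 (zero-force off rate);
parameter standard deviations are square roots of the diagonal of the fit
covariance matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import gaussian_kde

from .bellevans import (
    KBT_ROOM,
    BellEvansParams,
    bell_evans_survival,
    most_probable_force,
)


@dataclass
class RuptureDataset:
    """Rupture forces + loading rates pooled per construct x condition x speed."""

    forces: np.ndarray  # pN
    loading_rates: np.ndarray  # pN/s
    construct: str = ""
    condition: str = "apo"  # apo | bound | control
    pulling_speed: float = math.nan  # nm/s

    def __post_init__(self) -> None:
        self.forces = np.asarray(self.forces, dtype=float)
        self.loading_rates = np.asarray(self.loading_rates, dtype=float)
        if self.forces.shape != self.loading_rates.shape:
            raise ValueError("forces and loading_rates must have the same length")

    @property
    def n(self) -> int:
        return int(self.forces.size)

    @property
    def typical_loading_rate(self) -> float:
        """Geometric-mean loading rate (rates are log-distributed)."""
        return float(np.exp(np.mean(np.log(self.loading_rates))))


@dataclass
class HistogramFit:
    params: BellEvansParams
    param_sds: tuple[float, float]  # (sd_dx nm, sd_k0 1/s)
    bin_size: float
    loading_rate_used: float
    most_probable_force: float  # closed-form mode at the fitted params
    converged: bool
    reduced_chi2: float = math.nan
    n: int = 0
    message: str = ""


@dataclass
class KDEResult:
    bandwidth: float  # pN
    modes: list[float]  # ascending, at most two
    densities: list[float]  # density at each mode


@dataclass
class DFSFit:
    params: BellEvansParams
    param_sds: tuple[float, float]
    loading_rates: list[float]  # per-speed most probable loading rate (pN/s)
    forces: list[float]  # per-speed most probable force (pN)
    fwhms: list[float]  # per-speed force FWHM (pN)
    speeds: list[float] = field(default_factory=list)  # nm/s


def fit_bell_evans_histogram(data: RuptureDataset, bin_size: float = 25.0,
                             loading_rate: float | None = None,
                             kBT: float = KBT_ROOM,
                             bin_origin: float = 0.0) -> HistogramFit:
    """Least-squares Bell-Evans fit to the density-normalized force histogram.

    Bins of width ``bin_size`` pN span [bin_origin, max + 2 bins]; the
    per-bin densities are fitted with the *bin-averaged* Bell-Evans
    density — (S(lo) - S(hi)) / width from the closed-form survival — at
    the dataset's typical loading rate (Levenberg-Marquardt, as the model
    is nonlinear in dx).  Averaging over the bin rather than evaluating the
    density at the bin center keeps the fit unbiased even when the bin is
    as wide as the distribution itself.  Standard deviations come from the
    covariance diagonal.  Non-convergence is reported, never silent.
    """
    if data.n < 50:
        warnings.warn(f"only {data.n} rupture forces; histogram fit may be unstable",
                      stacklevel=2)
    r = loading_rate if loading_rate is not None else data.typical_loading_rate
    lo = min(bin_origin, float(np.min(data.forces)))
    edges = np.arange(lo, float(np.max(data.forces)) + 2 * bin_size, bin_size)
    counts, edges = np.histogram(data.forces, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = counts / (data.n * bin_size)

    # moment-based start: Bell-Evans forces are Gumbel-like with
    # SD = (pi/sqrt 6) * kBT/dx, mode given by the closed form
    sd = float(np.std(data.forces))
    dx0 = (math.pi / math.sqrt(6.0)) * kBT / max(sd, 1e-3)
    mode0 = float(np.median(data.forces))
    k00 = r * dx0 / kBT * math.exp(-mode0 * dx0 / kBT)

    def model(F, dx, k0):
        if dx <= 0 or k0 <= 0:
            return np.full_like(F, 1e6)
        p = BellEvansParams(dx, k0, kBT)
        s = bell_evans_survival(edges, p, r)
        return (s[:-1] - s[1:]) / bin_size

    try:
        popt, pcov = curve_fit(model, centers, density, p0=[dx0, k00],
                               method="lm", maxfev=20000)
        converged = np.all(np.isfinite(pcov))
        message = ""
    except RuntimeError as exc:  # pragma: no cover - pathological data
        return HistogramFit(BellEvansParams(dx0, k00, kBT), (math.nan, math.nan),
                            bin_size, r, math.nan, False, n=data.n, message=str(exc))
    params = BellEvansParams(float(abs(popt[0])), float(abs(popt[1])), kBT)
    sds = (float(np.sqrt(pcov[0, 0])), float(np.sqrt(pcov[1, 1])))
    resid = density - model(centers, *popt)
    # Poisson variance of counts propagated to density units
    var = np.maximum(counts, 1.0) / (data.n * bin_size) ** 2
    dof = max(centers.size - 2, 1)
    red_chi2 = float(np.sum(resid**2 / var) / dof)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mode = most_probable_force(params, r)
    return HistogramFit(params, sds, bin_size, r, mode, bool(converged),
                        reduced_chi2=red_chi2, n=data.n)


def kde_modes(forces, bandwidth: float | None = None,
              rel_threshold: float = 0.10, grid_points: int = 2048) -> KDEResult:
    """Most probable force(s) from a Gaussian kernel density estimate.

    Bandwidth defaults to Silverman's rule.  Local maxima with density of
    at least ``rel_threshold`` of the global maximum qualify; the two
    highest are reported, sorted ascending (one for unimodal data).
    """
    f = np.asarray(getattr(forces, "forces", forces), dtype=float)
    if f.size < 2 or np.ptp(f) == 0.0:
        val = float(f[0]) if f.size else math.nan
        return KDEResult(bandwidth=0.0, modes=[val], densities=[math.inf])
    kde = gaussian_kde(f, bw_method=bandwidth / np.std(f, ddof=1)
                       if bandwidth is not None else "silverman")
    h = float(kde.factor * np.std(f, ddof=1))
    grid = np.linspace(f.min() - 3 * h, f.max() + 3 * h, grid_points)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.nonzero(interior)[0] + 1
    peaks = peaks[dens[peaks] >= rel_threshold * dens.max()]
    if peaks.size == 0:  # monotone density; fall back to global max
        peaks = np.array([int(np.argmax(dens))])
    order = np.argsort(dens[peaks])[::-1][:2]
    chosen = np.sort(peaks[order])
    # quadratic refinement of each grid maximum
    modes, densities = [], []
    for p in chosen:
        if 0 < p < grid_points - 1:
            y0, y1, y2 = dens[p - 1], dens[p], dens[p + 1]
            denom = y0 - 2 * y1 + y2
            shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            x = grid[p] + shift * (grid[1] - grid[0])
        else:
            x = grid[p]
        modes.append(float(x))
        densities.append(float(kde(x)[0]))
    return KDEResult(bandwidth=h, modes=modes, densities=densities)


def kde_fwhm(forces, mode: float | None = None,
             bandwidth: float | None = None, grid_points: int = 2048) -> float:
    """Full width at half maximum of the force KDE around its principal mode."""
    f = np.asarray(getattr(forces, "forces", forces), dtype=float)
    kde = gaussian_kde(f, bw_method=bandwidth / np.std(f, ddof=1)
                       if bandwidth is not None else "silverman")
    h = float(kde.factor * np.std(f, ddof=1))
    grid = np.linspace(f.min() - 4 * h, f.max() + 4 * h, grid_points)
    dens = kde(grid)
    peak_idx = int(np.argmax(dens)) if mode is None else int(np.argmin(np.abs(grid - mode)))
    half = dens[peak_idx] / 2.0
    left = peak_idx
    while left > 0 and dens[left] > half:
        left -= 1
    right = peak_idx
    while right < grid_points - 1 and dens[right] > half:
        right += 1
    return float(grid[right] - grid[left])


def most_probable_loading_rate(loading_rates) -> float:
    """KDE mode of ln(r); loading rates are log-distributed."""
    r = np.asarray(getattr(loading_rates, "loading_rates", loading_rates), dtype=float)
    if r.size < 2 or np.ptp(r) == 0.0:
        return float(r[0])
    res = kde_modes(np.log(r))
    ln_mode = res.modes[int(np.argmax(res.densities))]
    return float(np.exp(ln_mode))


def fit_dfs(points: list[tuple[float, float]], kBT: float = KBT_ROOM,
            fwhms: list[float] | None = None,
            speeds: list[float] | None = None) -> DFSFit:
    """Fit the most-probable-force vs loading-rate relation.

    ``points`` holds (loading rate pN/s, most probable force pN) per
    pulling speed.  The model F*(r) = (kBT/dx) ln(r dx/(k0 kBT)) is fitted
    unweighted by Levenberg-Marquardt in (ln r, F) coordinates; the slope
    equals kBT/dx.  At least two distinct loading rates are required.
    """
    rates = np.asarray([p[0] for p in points], dtype=float)
    forces = np.asarray([p[1] for p in points], dtype=float)
    if rates.size < 2 or np.unique(rates).size < 2:
        raise ValueError("dynamic force spectrum needs >= 2 distinct loading rates")
    if np.any(rates <= 0):
        raise ValueError("loading rates must be positive")
    ln_r = np.log(rates)

    slope, intercept = np.polyfit(ln_r, forces, 1)
    if slope <= 0:
        raise ValueError("forces do not increase with loading rate; no Bell-Evans fit")
    dx0 = kBT / slope
    k00 = dx0 / kBT * math.exp(-intercept / slope)

    def model(lr, dx, k0):
        return kBT / dx * (lr + np.log(dx / (k0 * kBT)))

    popt, pcov = curve_fit(model, ln_r, forces, p0=[dx0, k00], method="lm",
                           maxfev=20000)
    params = BellEvansParams(float(abs(popt[0])), float(abs(popt[1])), kBT)
    sds = (float(np.sqrt(pcov[0, 0])), float(np.sqrt(pcov[1, 1])))
    return DFSFit(params, sds, list(rates), list(forces),
                  list(fwhms) if fwhms else [math.nan] * rates.size,
                  list(speeds) if speeds else [])


def dfs_from_datasets(datasets: list[RuptureDataset], kBT: float = KBT_ROOM) -> DFSFit:
    """Build and fit a dynamic force spectrum from per-speed rupture datasets."""
    pts, fwhms, speeds = [], [], []
    for ds in sorted(datasets, key=lambda d: d.typical_loading_rate):
        mode_r = most_probable_loading_rate(ds)
        res = kde_modes(ds)
        mode_f = res.modes[int(np.argmax(res.densities))]
        pts.append((mode_r, mode_f))
        fwhms.append(kde_fwhm(ds, mode=mode_f))
        speeds.append(ds.pulling_speed)
    return fit_dfs(pts, kBT=kBT, fwhms=fwhms, speeds=speeds)


@dataclass
class ConditionShift:
    force_apo: float
    force_bound: float

    @property
    def delta(self) -> float:
        return self.force_bound - self.force_apo

    @property
    def percent(self) -> float:
        return 100.0 * self.delta / self.force_apo


def mode_standard_error(forces, n_boot: int = 200, seed: int = 0) -> float:
    """Bootstrap standard error of the principal KDE mode."""
    f = np.asarray(getattr(forces, "forces", forces), dtype=float)
    if f.size < 10 or np.ptp(f) == 0.0:
        return math.nan
    rng = np.random.default_rng(seed)
    modes = np.empty(n_boot)
    for b in range(n_boot):
        res = kde_modes(rng.choice(f, size=f.size, replace=True))
        modes[b] = res.modes[int(np.argmax(res.densities))]
    return float(np.std(modes, ddof=1))


def _extract_modes(result) -> list[float]:
    if isinstance(result, HistogramFit):
        return [result.most_probable_force]
    if isinstance(result, KDEResult):
        return list(result.modes)
    if isinstance(result, (int, float)):
        return [float(result)]
    if isinstance(result, (list, tuple)) and result:
        return [float(x) for x in result]
    raise TypeError(f"cannot extract most probable force from {type(result).__name__}")


def compare_conditions(apo, bound) -> list[ConditionShift]:
    """Most-probable-force shift(s) upon ligand binding.

    One :class:`ConditionShift` per apo mode (two for a bimodal apo
    distribution), each against the principal bound mode.  Swapping the
    arguments negates each shift.
    """
    apo_modes = _extract_modes(apo)
    bound_modes = _extract_modes(bound)
    bound_f = bound_modes[0] if len(bound_modes) == 1 else bound_modes[-1]
    return [ConditionShift(force_apo=fa, force_bound=bound_f) for fa in apo_modes]
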