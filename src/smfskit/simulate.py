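"""Synthetic constant-velocity AFM pulling curves.

Generates force-distance traces of a polyprotein stretched between a
Hookean cantilever and a surface: at every time step the piezo displacement
``D = v*t`` is partitioned between cantilever deflection ``d`` and polymer
extension ``x = D - d`` by force balance ``k*d = F_wlc(x; Lc)``.  Each
foldable domain carries Bell kinetics; its unfolding hazard
``k(F) = k0*exp(F*dx/kBT)`` is integrated along the trajectory and the
domain unfolds when the accumulated hazard crosses an Exp(1) threshold,
releasing its contour-length increment.  A final receptor-ligand handle
rupture drops the force to the baseline.  Gaussian force noise, a linear
baseline drift and a multiplicative deflection-calibration (InvOLS) error
are applied last; the ground truth records the noise-free rupture forces,
loading rates and increments so that downstream detection can be scored.

The measured polyprotein mimics the construct used for mechanical
phenotyping of cohesins: a ddFLN4 fingerprint domain (34 nm release in two
substeps), the cohesin under study (45 nm release), and a high-force
cohesin-dockerin pulling handle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .bellevans import KBT_ROOM, BellEvansParams, sample_rupture_forces  # noqa: F401
from .wlc import DEFAULT_LP


@dataclass(frozen=True)
class SegmentSpec:
    """One segment of the polyprotein chain.

    ``kinetics=None`` marks a segment that never unfolds (linkers, the
    pulling-handle backbone).  Multi-step unfolders list their per-substep
    contour-length releases in ``substep_increments``; these must sum to
    ``contour_length_increment``.
    """

    name: str
    contour_length_folded: float  # nm contributed while folded
    contour_length_increment: float = 0.0  # nm released by complete unfolding
    kinetics: BellEvansParams | None = None
    substep_increments: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.contour_length_folded < 0 or self.contour_length_increment < 0:
            raise ValueError(f"segment {self.name}: contour lengths must be >= 0")
        if self.substep_increments:
            if any(s < 0 for s in self.substep_increments):
                raise ValueError(f"segment {self.name}: substep increments must be >= 0")
            if not math.isclose(sum(self.substep_increments),
                                self.contour_length_increment, rel_tol=1e-9):
                raise ValueError(
                    f"segment {self.name}: substep increments must sum to the total increment")

    @property
    def steps(self) -> tuple[float, ...]:
        """Per-substep increments (a single step if none were specified)."""
        if self.substep_increments:
            return self.substep_increments
        return (self.contour_length_increment,) if self.contour_length_increment else ()


# Default kinetics: the fingerprint unfolds at low force (~80 pN at
# 2e4 pN/s), the default cohesin at ~140 pN, the handle unbinds ~650 pN.
DDFLN4_KINETICS = BellEvansParams(delta_x=0.45, k0=0.35)
DEFAULT_COHESIN_KINETICS = BellEvansParams(delta_x=0.34, k0=1.3e-2)
DEFAULT_HANDLE_KINETICS = BellEvansParams(delta_x=0.13, k0=4.0e-6)

DDFLN4_INCREMENT = 34.0  # nm, two-step release 15 + 19
COHESIN_INCREMENT = 45.0  # nm


def fingerprint_construct(
    cohesin_kinetics: BellEvansParams = DEFAULT_COHESIN_KINETICS,
) -> list[SegmentSpec]:
    """Linker + ddFLN4 fingerprint + cohesin, the standard pulling construct."""
    return [
        SegmentSpec("linker", contour_length_folded=35.0),
        SegmentSpec("ddFLN4", contour_length_folded=4.0,
                    contour_length_increment=DDFLN4_INCREMENT,
                    kinetics=DDFLN4_KINETICS,
                    substep_increments=(15.0, 19.0)),
        SegmentSpec("cohesin", contour_length_folded=4.0,
                    contour_length_increment=COHESIN_INCREMENT,
                    kinetics=cohesin_kinetics),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one simulated pulling cycle."""

    segments: tuple[SegmentSpec, ...] = ()
    handle_rupture: BellEvansParams = DEFAULT_HANDLE_KINETICS
    spring_constant: float = 143.0  # pN/nm
    pulling_speed: float = 1600.0  # nm/s
    noise_sd: float = 6.0  # pN, per-sample Gaussian
    baseline_offset: float = 0.0  # pN
    baseline_drift_rate: float = 2.0  # pN/s, linear in time
    invols_error: float = 1.0  # multiplicative deflection-scale miscalibration
    sampling_rate: float = 1e4  # Hz
    persistence_length: float = DEFAULT_LP  # nm, shared by the serial chain
    max_force: float = 1500.0  # pN, safety cap ending runaway traces
    seed: int | None = None
    construct: str = "construct"
    condition: str = "apo"

    def __post_init__(self) -> None:
        if not self.segments:
            object.__setattr__(self, "segments", tuple(fingerprint_construct()))
        else:
            object.__setattr__(self, "segments", tuple(self.segments))
        for name in ("spring_constant", "pulling_speed", "sampling_rate",
                     "persistence_length", "invols_error"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ForceCurve:
    """One recorded pulling trace.

    ``deflection`` is the recorded cantilever deflection in nm (which is
    what the instrument's photodiode calibration yields, and where all
    measurement artifacts live); force in pN is derived as
    ``deflection * spring_constant``.  Tip-sample separation is
    ``piezo_position - deflection``.
    """

    time: np.ndarray  # s
    piezo_position: np.ndarray  # nm
    deflection: np.ndarray  # nm
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        z = np.asarray(self.piezo_position, dtype=float)
        d = np.asarray(self.deflection, dtype=float)
        if not (t.shape == z.shape == d.shape and t.ndim == 1):
            raise ValueError("time, piezo_position and deflection must be equal-length 1-D arrays")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "piezo_position", z)
        object.__setattr__(self, "deflection", d)

    @property
    def spring_constant(self) -> float:
        return float(self.metadata["spring_constant"])

    @property
    def force(self) -> np.ndarray:
        """Force in pN."""
        return self.deflection * self.spring_constant

    @property
    def separation(self) -> np.ndarray:
        """Tip-sample separation (nm)."""
        return self.piezo_position - self.deflection

    def with_deflection(self, deflection: np.ndarray, step: str | None = None) -> "ForceCurve":
        """Copy with a new deflection array; records ``step`` under metadata['processing']."""
        meta = dict(self.metadata)
        if step is not None:
            meta["processing"] = list(meta.get("processing", [])) + [step]
        return ForceCurve(self.time.copy(), self.piezo_position.copy(),
                          np.asarray(deflection, dtype=float), meta)

    def with_force(self, force: np.ndarray, step: str | None = None) -> "ForceCurve":
        return self.with_deflection(np.asarray(force, dtype=float) / self.spring_constant, step)


@dataclass(frozen=True)
class TrueEvent:
    """Ground-truth record of one unfolding/rupture."""

    index: int  # sample index at which the rupture occurred
    segment: str  # e.g. "ddFLN4/1", "cohesin", "handle"
    rupture_force: float  # pN, noise-free
    loading_rate: float  # pN/s, noise-free dF/dt just before rupture
    increment: float  # nm released (0 for the handle)


@dataclass(frozen=True)
class GroundTruth:
    events: tuple[TrueEvent, ...]

    @property
    def handle_rupture_force(self) -> float | None:
        for ev in self.events:
            if ev.segment == "handle":
                return ev.rupture_force
        return None

    def increments(self, segment_prefix: str) -> list[float]:
        return [ev.increment for ev in self.events if ev.segment.startswith(segment_prefix)]


def _solve_deflection(D: float, Lc: float, k: float, c: float, d0: float) -> float:
    """Root of k*d = F_wlc(D - d; Lc) for the deflection d.

    ``c = kBT/Lp``.  Strictly monotone in d, so a damped Newton iteration
    from the previous time step's solution converges; falls back to
    bisection on the bracket if Newton leaves it.
    """
    lo = max(0.0, D - Lc * (1.0 - 1e-9))
    hi = D
    d = min(max(d0, lo), hi)
    for _ in range(100):
        x = D - d
        rel = x / Lc
        if rel >= 1.0:  # numerical guard; cannot occur inside the bracket
            rel = 1.0 - 1e-12
        om = 1.0 - rel
        f = k * d - c * (0.25 / (om * om) - 0.25 + rel)
        if f > 0.0:
            hi = d
        else:
            lo = d
        df = k + c * (0.5 / (om * om * om) + 1.0) / Lc
        d_new = d - f / df
        if not (lo < d_new < hi):
            d_new = 0.5 * (lo + hi)
        if abs(d_new - d) < 1e-12:
            return d_new
        d = d_new
    if hi - lo > 1e-6:
        raise RuntimeError(f"force balance did not converge at D={D:.3f} nm")
    return d


def simulate_curve(config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> tuple[ForceCurve, GroundTruth]:
    """Simulate one constant-velocity retraction.

    Returns the recorded curve (with noise, drift and InvOLS error applied)
    and the noise-free ground truth.  Bit-identical output for identical
    config (including seed).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    k = config.spring_constant
    v = config.pulling_speed
    dt = 1.0 / config.sampling_rate
    kBT = KBT_ROOM
    c = kBT / config.persistence_length

    Lc = sum(s.contour_length_folded for s in config.segments)
    if Lc <= 0:
        raise ValueError("total folded contour length must be positive")

    # pending (kinetics, increment, label) substep queues per foldable segment,
    # plus the final handle rupture
    queues: list[list[tuple[BellEvansParams, float, str]]] = []
    for seg in config.segments:
        if seg.kinetics is not None and seg.steps:
            labels = ([seg.name] if len(seg.steps) == 1
                      else [f"{seg.name}/{i + 1}" for i in range(len(seg.steps))])
            queues.append([(seg.kinetics, inc, lab) for inc, lab in zip(seg.steps, labels)])
    handle = (config.handle_rupture, 0.0, "handle")

    # Exp(1) hazard thresholds, drawn up-front in a fixed order for determinism
    n_thresholds = sum(len(q) for q in queues) + 1
    thresholds = iter(rng.exponential(size=n_thresholds))
    active: list[dict] = []  # {kinetics, increment, label, queue, threshold, hazard}

    def _activate(item, queue):
        kin, inc, lab = item
        active.append({"kin": kin, "inc": inc, "label": lab, "queue": queue,
                       "E": next(thresholds), "H": 0.0})

    for q in queues:
        _activate(q.pop(0), q)
    _activate(handle, None)

    times: list[float] = []
    piezo: list[float] = []
    force_true: list[float] = []
    exts: list[float] = []
    events: list[TrueEvent] = []
    detached = False
    d = 0.0
    i = 0
    # ground-truth loading rate = dF/dt over the last ~3 nm of polymer
    # extension before rupture, the same window convention as the
    # event-level estimator
    rate_window_nm = 3.0
    last_event_step = 0

    while True:
        t = i * dt
        D = v * t
        if detached:
            F = 0.0
        else:
            d = _solve_deflection(D, Lc, k, c, d)
            F = k * d
        times.append(t)
        piezo.append(D)
        force_true.append(F)
        exts.append(D - d if not detached else D)

        if not detached:
            fired = None
            F_prev = force_true[-2] if len(force_true) >= 2 else F
            for a in active:
                kin = a["kin"]
                H_before = a["H"]
                a["H"] += kin.k0 * math.exp(F * kin.delta_x / kin.kBT) * dt
                if fired is None and a["H"] >= a["E"]:
                    fired = a
                    # sub-step interpolation of the rupture force: the hazard
                    # crossed the threshold partway through this step
                    dH = a["H"] - H_before
                    frac = (a["E"] - H_before) / dH if dH > 0 else 1.0
                    fired_force = F_prev + (F - F_prev) * min(max(frac, 0.0), 1.0)
            if fired is not None:
                # fit dF/dt over samples within the extension window,
                # restricted to the current (post-previous-event) segment
                x_now = exts[-1]
                j0 = last_event_step
                while j0 < i and exts[j0] < x_now - rate_window_nm:
                    j0 += 1
                if i + 1 - j0 >= 2:
                    tt = np.asarray(times[j0:i + 1])
                    ff = np.asarray(force_true[j0:i + 1])
                    rate = float(np.polyfit(tt, ff, 1)[0])
                else:
                    rate = k * v
                # index the event at the last fully-loaded sample
                events.append(TrueEvent(index=max(i - 1, 0), segment=fired["label"],
                                        rupture_force=fired_force, loading_rate=rate,
                                        increment=fired["inc"]))
                # the rupture happened within this sampling interval, so the
                # current sample already shows the post-rupture force
                if fired["label"] == "handle":
                    detached = True
                    d = 0.0
                    force_true[-1] = 0.0
                    exts[-1] = D
                else:
                    Lc += fired["inc"]
                    if fired["queue"]:
                        _activate(fired["queue"].pop(0), fired["queue"])
                    active.remove(fired)
                    d = _solve_deflection(D, Lc, k, c, d)
                    force_true[-1] = k * d
                    exts[-1] = D - d
                last_event_step = i + 1
            if F > config.max_force:
                break  # runaway trace (handle never ruptured); ends without detachment
        else:
            # post-detachment baseline tail: 15% of the loaded portion,
            # at least 10 ms, so baseline correction has a window to work on
            n_loaded = events[-1].index if events else i
            if i >= n_loaded + max(int(0.15 * n_loaded), int(0.01 / dt)):
                break
        i += 1

    t_arr = np.asarray(times)
    z_arr = np.asarray(piezo)
    F_arr = np.asarray(force_true)

    # measurement artifacts, applied to the recorded deflection signal
    noise = rng.normal(0.0, config.noise_sd, size=F_arr.size) if config.noise_sd > 0 else 0.0
    drift = config.baseline_offset + config.baseline_drift_rate * t_arr
    deflection = (config.invols_error * F_arr + drift + noise) / k

    meta = {
        "spring_constant": k,
        "pulling_speed": v,
        "sampling_rate": config.sampling_rate,
        "invols": config.invols_error,
        "persistence_length": config.persistence_length,
        "construct": config.construct,
        "condition": config.condition,
        "seed": config.seed,
    }
    curve = ForceCurve(t_arr, z_arr, deflection, meta)
    return curve, GroundTruth(tuple(events))


def simulate_ensemble(config: SimulationConfig, n_curves: int,
                      seed: int) -> list[tuple[ForceCurve, GroundTruth]]:
    """Simulate ``n_curves`` independent pulling cycles from one master seed."""
    child_seeds = np.random.SeedSequence(seed).generate_state(n_curves) % (2**31)
    out = []
    for s in child_seeds:
        cfg = replace(config, seed=int(s))
        out.append(simulate_curve(cfg))
    return out


# ---------------------------------------------------------------------------
# plain-text I/O


def write_curve(curve: ForceCurve, path: str | Path) -> None:
    """Write a curve as tab-separated time_s / piezo_nm / deflection_nm with
    ``# key=value`` metadata header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in curve.metadata.items():
            if key == "processing":
                val = ";".join(map(str, val))
            fh.write(f"# {key}={val}\n")
        fh.write("time_s\tpiezo_nm\tdeflection_nm\n")
        for t, z, d in zip(curve.time, curve.piezo_position, curve.deflection):
            fh.write(f"{t:.9g}\t{z:.9g}\t{d:.9g}\n")


def read_curve(path: str | Path) -> ForceCurve:
    meta: dict = {}
    rows: list[tuple[float, float, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                try:
                    parsed: object = json.loads(val)
                except (json.JSONDecodeError, ValueError):
                    parsed = val
                meta[key.strip()] = parsed
            elif line[0].isdigit() or line[0] in "+-.":
                a, b, cc = line.split("\t")
                rows.append((float(a), float(b), float(cc)))
    arr = np.asarray(rows)
    return ForceCurve(arr[:, 0], arr[:, 1], arr[:, 2], meta)


def write_ground_truth(truths: dict[str, GroundTruth], path: str | Path) -> None:
    """Tab-separated ground-truth event table keyed by curve id."""
    with open(path, "w") as fh:
        fh.write("curve_id\tsegment\trupture_force_pN\tloading_rate_pN_s\tincrement_nm\n")
        for curve_id, gt in truths.items():
            for ev in gt.events:
                fh.write(f"{curve_id}\t{ev.segment}\t{ev.rupture_force:.6g}"
                         f"\t{ev.loading_rate:.6g}\t{ev.increment:.6g}\n")


def write_manifest(entries: list[dict], path: str | Path) -> None:
    """JSON manifest listing curve files with construct/condition/speed/seed."""
    with open(path, "w") as fh:
        json.dump({"curves": entries}, fh, indent=1, sort_keys=True)
        fh.write("\n")
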