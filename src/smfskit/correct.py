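"""Corrections applied to raw pulling curves before event detection.

Long automated AFM sessions accumulate laser-spot drift on the cantilever:
the recorded deflection picks up a slowly varying offset, and the
deflection calibration (inverse optical lever sensitivity, InvOLS) can
depart from the value of the calibration curve.  The corrections here are
the standard remedies: rescale by the known InvOLS ratio, remove the
baseline offset and drift estimated from the trailing (post-detachment)
part of each curve, and suppress single-sample noise spikes with a moving
median.  All three are pure functions returning corrected copies; the
canonical order is InvOLS -> baseline -> median (see
:func:`standard_corrections`).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import median_filter

from .simulate import ForceCurve


def correct_invols(curve: ForceCurve, reference_invols: float,
                   measured_invols: float) -> ForceCurve:
    """Rescale deflection (hence force) by ``reference/measured``.

    Exact and linear; applying the inverse ratio afterwards restores the
    original curve.
    """
    if not (reference_invols > 0 and measured_invols > 0):
        raise ValueError("InvOLS scales must be positive")
    ratio = reference_invols / measured_invols
    return curve.with_deflection(curve.deflection * ratio,
                                 step=f"invols(ratio={ratio:.6g})")


def correct_baseline(curve: ForceCurve, baseline_fraction: float = 0.05,
                     fit_drift: bool = False) -> ForceCurve:
    """Zero the force baseline using the trailing ``baseline_fraction`` of samples.

    By default the mean of the trailing window (after the final detachment
    the force is pure baseline) is subtracted as a per-curve offset — this
    is what absorbs slow session-scale laser drift, which is effectively
    constant within one sub-second curve.  ``fit_drift=True`` additionally
    fits and removes a linear-in-time slope; use it only on long or
    low-noise curves, since a slope estimated from a short noisy tail
    extrapolates poorly to the start of the trace.  After correction the
    trailing-window mean is zero up to numerical tolerance.
    """
    n = curve.time.size
    if n < 20:
        raise ValueError("curve too short for baseline correction (< 20 samples)")
    w = int(round(n * baseline_fraction))
    if w < 3:
        raise ValueError(
            f"baseline window has {w} samples (< 3); increase baseline_fraction")
    t_tail = curve.time[-w:]
    f_tail = curve.force[-w:]
    if fit_drift:
        slope, offset = np.polyfit(t_tail, f_tail, 1)
    else:
        slope, offset = 0.0, float(np.mean(f_tail))
    corrected = curve.force - (offset + slope * curve.time)
    return curve.with_force(
        corrected, step=f"baseline(fraction={baseline_fraction},"
                        f"offset={offset:.4g}pN,slope={slope:.4g}pN/s)")


def smooth_median(curve: ForceCurve, window: int = 11) -> ForceCurve:
    """Moving-median smoothing of the force channel.

    Robust to single-sample spikes of any amplitude; edges use a reflected
    (effectively shrinking) window.  Window must be odd so the median sits
    on a sample.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window!r}")
    smoothed = median_filter(curve.force, size=window, mode="nearest")
    return curve.with_force(smoothed, step=f"median(window={window})")


def standard_corrections(curve: ForceCurve, reference_invols: float = 1.0,
                         baseline_fraction: float = 0.05,
                         median_window: int = 11) -> ForceCurve:
    """InvOLS -> baseline -> median, the default preprocessing chain.

    The per-curve InvOLS is taken from ``curve.metadata['invols']`` when
    present (1.0 otherwise), i.e. the calibration bookkeeping travels with
    the curve file.
    """
    measured = float(curve.metadata.get("invols", 1.0))
    out = correct_invols(curve, reference_invols, measured)
    out = correct_baseline(out, baseline_fraction=baseline_fraction)
    return smooth_median(out, window=median_window)
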