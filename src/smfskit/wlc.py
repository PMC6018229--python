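"""Worm-like-chain entropic elasticity (interpolated Marko-Siggia form).

Relates force F, end-to-end extension x, contour length Lc and persistence
length Lp:

    F(x) = (kBT/Lp) * [ 1/(4*(1 - x/Lc)^2) - 1/4 + x/Lc ]

The force is strictly increasing in x on [0, Lc) and diverges at x = Lc,
so both the forward map and its inverse (contour length from a measured
force/extension pair) are well defined.
"""

from __future__ import annotations

import numpy as np

from .bellevans import KBT_ROOM

#: Default polypeptide persistence length (nm).
DEFAULT_LP = 0.365


def wlc_force(extension, contour_length, persistence_length: float = DEFAULT_LP,
              kBT: float = KBT_ROOM):
    """Force (pN) of a WLC stretched to ``extension`` (nm).

    Vectorized over ``extension``; requires 0 <= x < Lc elementwise.
    """
    x = np.asarray(extension, dtype=float)
    Lc = np.asarray(contour_length, dtype=float)
    if np.any(Lc <= 0):
        raise ValueError("contour_length must be positive")
    rel = x / Lc
    if np.any(rel < 0) or np.any(rel >= 1):
        raise ValueError("extension must satisfy 0 <= x < contour_length")
    out = kBT / persistence_length * (0.25 / (1.0 - rel) ** 2 - 0.25 + rel)
    return out if out.ndim else float(out)


def wlc_stiffness(extension, contour_length, persistence_length: float = DEFAULT_LP,
                  kBT: float = KBT_ROOM):
    """dF/dx (pN/nm) of the Marko-Siggia WLC; used by force-balance solvers."""
    x = np.asarray(extension, dtype=float)
    rel = x / contour_length
    out = kBT / persistence_length * (0.5 / (1.0 - rel) ** 3 + 1.0) / contour_length
    return out if out.ndim else float(out)


def wlc_extension(force, contour_length, persistence_length: float = DEFAULT_LP,
                  kBT: float = KBT_ROOM):
    """Extension x (nm) at which the WLC carries ``force`` (pN).

    Inverts the Marko-Siggia relation for the relative extension.  The
    relation is a cubic in (1 - x/Lc); solved here by a guarded Newton
    iteration from a Hookean/asymptotic seed (converges to machine
    precision in a handful of steps since F is strictly increasing).
    """
    F = np.asarray(force, dtype=float)
    if np.any(F < 0):
        raise ValueError("force must be nonnegative")
    c = F * persistence_length / kBT  # dimensionless force
    # seed: interpolate between low-force Hookean (x/Lc = 2c/3) and
    # high-force asymptote (x/Lc = 1 - 1/(2*sqrt(c)))
    with np.errstate(divide="ignore"):
        hi = 1.0 - 0.5 / np.sqrt(np.maximum(c, 1e-300))
    rel = np.where(c < 1.0, 2.0 * c / 3.0, np.clip(hi, 0.0, 1.0 - 1e-12))
    rel = np.clip(rel, 0.0, 1.0 - 1e-12)
    for _ in range(60):
        g = 0.25 / (1.0 - rel) ** 2 - 0.25 + rel - c
        dg = 0.5 / (1.0 - rel) ** 3 + 1.0
        step = g / dg
        rel_new = np.clip(rel - step, 0.0, 1.0 - 1e-15)
        if np.all(np.abs(rel_new - rel) < 1e-15):
            rel = rel_new
            break
        rel = rel_new
    out = rel * contour_length
    return out if out.ndim else float(out)


def wlc_contour_length(force, extension, persistence_length: float = DEFAULT_LP,
                       kBT: float = KBT_ROOM):
    """Contour length Lc (nm) of a WLC observed at (force, extension).

    The unique Lc > x solving the Marko-Siggia relation; exact inverse of
    :func:`wlc_force` in its first argument.  Requires force > 0.
    """
    F = np.asarray(force, dtype=float)
    x = np.asarray(extension, dtype=float)
    if np.any(F <= 0):
        raise ValueError("force must be positive to invert for contour length")
    # Lc = x / rel where rel is the relative extension at this force
    rel = wlc_extension(F, 1.0, persistence_length, kBT)
    out = x / np.asarray(rel, dtype=float)
    return out if out.ndim else float(out)
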