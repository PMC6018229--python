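"""Bell-Evans rupture-force statistics.

A single folded domain (or a receptor-ligand bond) held under a force ramp
escapes over one force-tilted barrier at rate ``k(F) = k0 * exp(F*dx/kBT)``.
Under a constant loading rate ``r`` (pN/s) the rupture-force probability
density is

    p(F) = (k0/r) * exp[ (dx/kBT)*F - (k0*kBT/(r*dx)) * (exp(dx*F/kBT) - 1) ]

with ``dx`` the distance to the transition state (nm) and ``k0`` the
zero-force off rate (1/s).  The most probable rupture force grows linearly
with the logarithm of the loading rate,

    F*(r) = (kBT/dx) * ln(r*dx / (k0*kBT)),

which is the relation dynamic force spectra are fitted with.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

#: Thermal energy at 25 degC in pN*nm.
KBT_ROOM = 4.11


@dataclass(frozen=True)
class BellEvansParams:
    """Kinetic parameters of a single sharp barrier.

    Parameters
    ----------
    delta_x : float
        Distance to the transition state along the pulling coordinate (nm).
    k0 : float
        Zero-force off rate (1/s).
    kBT : float
        Thermal energy (pN*nm), default 4.11 (25 degC).
    """

    delta_x: float
    k0: float
    kBT: float = KBT_ROOM

    def __post_init__(self) -> None:
        for field in ("delta_x", "k0", "kBT"):
            value = getattr(self, field)
            if not (value > 0 and math.isfinite(value)):
                raise ValueError(f"{field} must be positive and finite, got {value!r}")

    def rate(self, force):
        """Force-dependent off rate ``k0 * exp(F*dx/kBT)`` (1/s)."""
        return self.k0 * np.exp(np.asarray(force, dtype=float) * self.delta_x / self.kBT)


def bell_evans_pdf(force, params: BellEvansParams, loading_rate: float):
    """Rupture-force probability density (1/pN) at constant loading rate.

    Vectorized over ``force``; negative forces have zero density assigned by
    the caller's convention — the analytic form is evaluated as-is (it is a
    valid density on [0, inf) and integrates to one there).
    """
    if not loading_rate > 0:
        raise ValueError(f"loading_rate must be positive, got {loading_rate!r}")
    F = np.asarray(force, dtype=float)
    beta = params.delta_x / params.kBT  # 1/pN
    scale = params.k0 * params.kBT / (loading_rate * params.delta_x)
    with np.errstate(over="ignore"):  # exp(-huge) underflows to 0 in the far tail
        return params.k0 / loading_rate * np.exp(beta * F - scale * np.expm1(beta * F))


def bell_evans_survival(force, params: BellEvansParams, loading_rate: float):
    """Probability that the bond is still intact at force ``F``."""
    if not loading_rate > 0:
        raise ValueError(f"loading_rate must be positive, got {loading_rate!r}")
    F = np.asarray(force, dtype=float)
    beta = params.delta_x / params.kBT
    scale = params.k0 * params.kBT / (loading_rate * params.delta_x)
    with np.errstate(over="ignore"):
        return np.exp(-scale * np.expm1(beta * F))


def sample_rupture_forces(
    params: BellEvansParams,
    loading_rate: float,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw i.i.d. rupture forces (pN) by exact inversion of the survival CDF.

    Setting the survival probability equal to a uniform variate U gives

        F = (kBT/dx) * ln(1 - (r*dx/(k0*kBT)) * ln U),

    which is nonnegative for U in (0, 1].
    """
    if not loading_rate > 0:
        raise ValueError(f"loading_rate must be positive, got {loading_rate!r}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.uniform(size=n)
    inv_scale = loading_rate * params.delta_x / (params.k0 * params.kBT)
    return params.kBT / params.delta_x * np.log1p(-inv_scale * np.log(u))


def most_probable_force(params: BellEvansParams, loading_rate: float) -> float:
    """Mode of the rupture-force distribution, closed form.

    Requires ``r*dx > k0*kBT``; below that the mode sits at zero force and
    0.0 is returned with a warning.
    """
    if not loading_rate > 0:
        raise ValueError(f"loading_rate must be positive, got {loading_rate!r}")
    arg = loading_rate * params.delta_x / (params.k0 * params.kBT)
    if arg <= 1.0:
        warnings.warn(
            "loading rate too low for an interior mode (r*dx <= k0*kBT); "
            "most probable force clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return params.kBT / params.delta_x * math.log(arg)
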