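"""Per-alveolus physics.

Each alveolus follows an exponential pressure--volume law

    V(Ptp) = Vmax - A * exp(-k * Ptp),        A = Vmax - Vmin,

where ``Ptp`` is the transpulmonary (distending) pressure in cm H2O,
``Vmax`` the volume at infinite inflation pressure, ``Vmin`` the volume at
zero inflation pressure, and ``k`` a shape factor setting the curvature.

In the upright lung Ptp decreases linearly from apex to base because lung
tissue (at a fraction ``rho_frac`` of water density) hangs in the
gravitational field; with density expressed as a water fraction the
hydrostatic gradient is simply ``rho_frac`` cm H2O per cm of depth.

On the deflation limb an airway closes wherever Ptp falls below the airway
closing pressure ``Ptm'``; alveoli distal to a closed airway hold their gas
at the volume they had at closure, independent of depth.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AlveolarParams",
    "PressureProfile",
    "ClosureRule",
    "Closure",
    "alveolar_volume",
    "ptp_at_depth",
    "closure_depth",
    "deflation_volume",
]


class Closure(enum.Enum):
    """Sentinel outcomes of the airway-closure rule.

    ``NONE``: Ptp exceeds the closing pressure everywhere, no airway closes.
    ``ALL``: the closing pressure is at or above the apical Ptp, every
    airway is closed.
    """

    NONE = "none"
    ALL = "all"


@dataclass(frozen=True)
class AlveolarParams:
    """Constitutive constants for one class of alveoli.

    Parameters
    ----------
    v_max : float
        Volume at infinite inflation pressure (microliters).
    v_min : float
        Volume at zero inflation pressure (microliters).
    k : float
        Shape factor of the exponential law (per cm H2O).
    """

    v_max: float
    v_min: float
    k: float
    a: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0 <= self.v_min < self.v_max):
            raise ValueError(
                f"require 0 <= v_min < v_max, got v_min={self.v_min}, v_max={self.v_max}"
            )
        if not self.k > 0:
            raise ValueError(f"shape factor k must be positive, got {self.k}")
        object.__setattr__(self, "a", self.v_max - self.v_min)

    @property
    def ratio(self) -> float:
        """Gas-trapping ratio Vmin/Vmax."""
        return self.v_min / self.v_max

    def scaled(self, factor: float) -> "AlveolarParams":
        """Common rescale of (v_max, v_min); leaves Vmin/Vmax and k unchanged."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return AlveolarParams(self.v_max * factor, self.v_min * factor, self.k)


@dataclass(frozen=True)
class PressureProfile:
    """Linear hydrostatic transpulmonary-pressure field over lung height.

    ``Ptp(z) = p_apex - rho_frac * z`` with depth ``z`` in cm measured from
    the apex downward. ``rho_frac`` is lung tissue density as a fraction of
    water density, so the gradient is ``rho_frac`` cm H2O per cm.
    """

    p_apex: float
    height: float
    rho_frac: float = 0.25

    def __post_init__(self) -> None:
        if not self.height > 0:
            raise ValueError(f"height must be positive, got {self.height}")
        if not (0 <= self.rho_frac <= 1):
            raise ValueError(f"rho_frac must lie in [0, 1], got {self.rho_frac}")
        if not math.isfinite(self.p_apex):
            raise ValueError("p_apex must be finite")

    @property
    def p_base(self) -> float:
        """Ptp at the lung base (z = height)."""
        return self.p_apex - self.rho_frac * self.height


@dataclass(frozen=True)
class ClosureRule:
    """Airway closing pressure Ptm' (cm H2O), a single constant for the lung."""

    p_tm: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.p_tm) and self.p_tm >= 0):
            raise ValueError(f"closing pressure must be finite and >= 0, got {self.p_tm}")


def alveolar_volume(params: AlveolarParams, ptp):
    """Alveolar volume (microliters) at transpulmonary pressure ``ptp``.

    Evaluates ``v_max - a*exp(-k*ptp)``; strictly increasing and concave in
    ``ptp``, bounded above by ``v_max``. Negative pressures extrapolate the
    exponential as written. Accepts scalars or arrays.
    """
    ptp = np.asarray(ptp, dtype=float)
    if not np.all(np.isfinite(ptp)):
        raise ValueError("transpulmonary pressure must be finite")
    v = params.v_max - params.a * np.exp(-params.k * ptp)
    return float(v) if v.ndim == 0 else v


def ptp_at_depth(profile: PressureProfile, z):
    """Transpulmonary pressure at depth ``z`` cm below the apex."""
    z = np.asarray(z, dtype=float)
    if np.any(z < 0) or np.any(z > profile.height):
        raise ValueError(f"depth must lie in [0, {profile.height}] cm")
    p = profile.p_apex - profile.rho_frac * z
    return float(p) if p.ndim == 0 else p


def closure_depth(profile: PressureProfile, rule: ClosureRule):
    """Depth below the apex at which airways close on deflation.

    Solves ``Ptp(z*) = Ptm'``. Returns ``Closure.ALL`` when the closing
    pressure meets or exceeds the apical Ptp (every airway closed),
    ``Closure.NONE`` when Ptp stays above Ptm' all the way to the base, and
    otherwise the unique interior depth z* in [0, height].
    """
    if rule.p_tm >= profile.p_apex:
        return Closure.ALL
    if rule.p_tm < profile.p_base:
        return Closure.NONE
    # rho_frac > 0 here: a constant profile hits one of the sentinels above.
    return (profile.p_apex - rule.p_tm) / profile.rho_frac


def deflation_volume(
    params: AlveolarParams, profile_deflation: PressureProfile, rule: ClosureRule, z
):
    """Alveolar volume at depth ``z`` on the deflation limb (microliters).

    Above the closure depth the airway is open and the volume follows the
    constitutive law at the local Ptp; at or below it the alveolus holds the
    gas trapped at closure, ``V(Ptm')``, independent of depth.
    """
    z_arr = np.asarray(z, dtype=float)
    ptp = ptp_at_depth(profile_deflation, z_arr)
    zstar = closure_depth(profile_deflation, rule)
    if zstar is Closure.NONE:
        closed = np.zeros(z_arr.shape, dtype=bool)
    elif zstar is Closure.ALL:
        closed = np.ones(z_arr.shape, dtype=bool)
    else:
        closed = z_arr >= zstar
    v = np.where(closed, alveolar_volume(params, rule.p_tm), alveolar_volume(params, ptp))
    return float(v) if v.ndim == 0 else v
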