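"""Calibration of the model's two free degrees of freedom.

The static physiology fixes everything except (1) the apical
transpulmonary pressure on the deflation limb and (2) the absolute
alveolar volume scale. Whole-lung RV/TLC depends on the first but — by
exact ratio invariance — not on the second, so the two are resolved
sequentially against two anchors:

* deflation pressure: deterministic Brent root-finding of
  ``rv_tlc(p_rv_apex) − target`` over a fixed bracket;
* volume scale: the closed form ``target_rv / rv(scale=1)``, exact because
  whole-lung RV is strictly proportional to a common (Vmax, Vmin) scale.

A closure-depth target is also supported (used by the healthy preset to
put closure exactly at the lung base); it inverts the linear hydrostatic
relation in closed form.

Calibrated parameters are frozen before any treatment simulation; the
post-treatment outputs are predictions, not fits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

from scipy.optimize import brentq

from .scenarios import ScenarioSpec

__all__ = [
    "CalibrationTarget",
    "CalibrationResult",
    "UnattainableTargetError",
    "calibrate_deflation_pressure",
    "calibrate_volume_scale",
    "calibrate_scenario",
]

Quantity = Literal["rv_tlc", "rv_liters", "closure_depth_cm"]


class UnattainableTargetError(ValueError):
    """Target value outside the range attainable over the search bracket."""


@dataclass(frozen=True)
class CalibrationTarget:
    quantity: Quantity
    value: float
    tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if not self.tolerance > 0:
            raise ValueError("tolerance must be positive")
        if self.quantity not in ("rv_tlc", "rv_liters", "closure_depth_cm"):
            raise ValueError(f"unknown calibration quantity {self.quantity!r}")
        if self.quantity == "rv_tlc" and not (0 < self.value < 1):
            raise UnattainableTargetError(
                f"rv_tlc anchor {self.value} is unattainable: whole-lung RV/TLC "
                "lies strictly inside (0, 1)"
            )
        if self.quantity == "rv_liters" and not self.value > 0:
            raise ValueError("rv target must be positive")


@dataclass(frozen=True)
class CalibrationResult:
    """Calibrated parameter with provenance."""

    parameter: str
    value: float
    target: CalibrationTarget
    achieved: float
    iterations: int

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "value": self.value,
            "anchor_quantity": self.target.quantity,
            "anchor_value": self.target.value,
            "achieved": self.achieved,
            "iterations": self.iterations,
        }


def _rv_tlc_at(scenario: ScenarioSpec, p_rv_apex: float) -> float:
    return replace(scenario, p_rv_apex=p_rv_apex).run().summary.rv_tlc


def calibrate_deflation_pressure(
    scenario: ScenarioSpec,
    target: CalibrationTarget,
    bracket: tuple[float, float] | None = None,
) -> CalibrationResult:
    """Resolve the deflation-limb apical pressure against an anchor.

    For an ``rv_tlc`` target, Brent's method finds the root of
    ``rv_tlc(p_rv_apex) − value`` over ``bracket`` (default
    ``[p_tm − 2, p_tlc_apex − 0.5]`` cm H2O); whole-lung RV/TLC is strictly
    increasing in the deflation pressure over any physiological bracket,
    which is verified via the bracket endpoints. A ``closure_depth_cm``
    target is inverted in closed form, ``p_rv_apex = Ptm' + rho_frac * z*``.
    Raises :class:`UnattainableTargetError`, reporting the attainable
    interval, when the anchor lies outside it.
    """
    if target.quantity == "closure_depth_cm":
        if not (0 <= target.value <= scenario.height):
            raise UnattainableTargetError(
                f"closure depth target must lie in [0, {scenario.height}] cm"
            )
        p = scenario.p_tm + scenario.rho_frac * target.value
        return CalibrationResult("p_rv_apex", p, target, target.value, iterations=0)
    if target.quantity != "rv_tlc":
        raise ValueError("deflation-pressure calibration accepts rv_tlc or closure_depth_cm")

    lo, hi = bracket if bracket is not None else (scenario.p_tm - 2.0, scenario.p_tlc_apex - 0.5)
    f_lo = _rv_tlc_at(scenario, lo)
    f_hi = _rv_tlc_at(scenario, hi)
    attainable = (min(f_lo, f_hi), max(f_lo, f_hi))
    if not attainable[0] <= target.value <= attainable[1]:
        raise UnattainableTargetError(
            f"rv_tlc target {target.value} unattainable over bracket [{lo}, {hi}]; "
            f"attainable interval is [{attainable[0]:.6f}, {attainable[1]:.6f}]"
        )
    root, info = brentq(
        lambda p: _rv_tlc_at(scenario, p) - target.value,
        lo,
        hi,
        xtol=1e-12,
        rtol=8.881784197001252e-16,
        full_output=True,
    )
    achieved = _rv_tlc_at(scenario, root)
    if abs(achieved - target.value) > target.tolerance:
        raise UnattainableTargetError(
            f"root finder converged to rv_tlc={achieved}, outside tolerance {target.tolerance}"
        )
    return CalibrationResult("p_rv_apex", float(root), target, achieved, info.iterations)


def calibrate_volume_scale(scenario: ScenarioSpec, target: CalibrationTarget) -> CalibrationResult:
    """Resolve the common (Vmax, Vmin) scale so whole-lung RV hits an anchor.

    Whole-lung RV is exactly proportional to the scale while RV/TLC is
    exactly invariant to it, so the factor is the closed form
    ``target / rv(scale=1)``; no iteration is involved.
    """
    if target.quantity != "rv_liters":
        raise ValueError("volume-scale calibration requires an rv_liters target")
    rv_unscaled = scenario.run().summary.rv
    if rv_unscaled <= 0:
        raise ZeroDivisionError("degenerate scenario: whole-lung RV is zero at unit scale")
    factor = target.value / rv_unscaled
    achieved = scenario.with_scale(factor).run().summary.rv
    return CalibrationResult("volume_scale", factor, target, achieved, iterations=0)


def calibrate_scenario(
    scenario: ScenarioSpec,
    rv_tlc: float | None = None,
    rv_liters: float | None = None,
    tolerance: float = 1e-6,
) -> ScenarioSpec:
    """Apply deflation-pressure and/or volume-scale calibration in sequence.

    The deflation pressure is resolved first (it is volume-scale
    invariant); the scale is then exact. Returns the calibrated scenario.
    """
    out = scenario
    if rv_tlc is not None:
        res = calibrate_deflation_pressure(
            scenario, CalibrationTarget("rv_tlc", rv_tlc, tolerance)
        )
        out = replace(out, p_rv_apex=res.value)
    if rv_liters is not None:
        res = calibrate_volume_scale(out, CalibrationTarget("rv_liters", rv_liters, tolerance))
        out = out.with_scale(res.value)
    return out
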