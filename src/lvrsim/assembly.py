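"""Layered lung assembly and whole-lung integration.

The lung is a stack of horizontal layers from apex to base. Each layer
carries a count of identical alveoli and their constitutive parameters.
Regional inflation/deflation volumes are evaluated at layer midpoints
(midpoint rule); whole-lung TLC and RV are population-weighted sums,
converted from microliters per alveolus to liters. For uniform lungs a
closed-form integral of the constitutive law over height serves as an
analytic oracle for the discretized sums.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    AlveolarParams,
    Closure,
    ClosureRule,
    PressureProfile,
    alveolar_volume,
    closure_depth,
    ptp_at_depth,
)

__all__ = [
    "Layer",
    "LungState",
    "InflationDeflationPressures",
    "RegionalProfile",
    "LungSummary",
    "InflationClosureError",
    "build_uniform_lung",
    "regional_profile",
    "lung_summary",
    "closed_form_totals",
    "DEFAULT_N_LAYERS",
]

#: Default discretization: 1 mm slabs over a 35 cm lung.
DEFAULT_N_LAYERS = 350

#: Fixed column order for per-layer CSV output.
PROFILE_COLUMNS = ["z_from_apex_cm", "z_from_base_cm", "n_alveoli", "v_tlc_ul", "v_rv_ul", "rv_tlc"]


class InflationClosureError(RuntimeError):
    """Raised when a scenario would close airways at full inflation."""


@dataclass(frozen=True)
class Layer:
    z_top: float
    z_bottom: float
    n_alveoli: float
    params: AlveolarParams

    def __post_init__(self) -> None:
        if not self.z_top < self.z_bottom:
            raise ValueError("layer needs z_top < z_bottom")
        if self.n_alveoli < 0:
            raise ValueError("layer alveolar count must be >= 0")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.z_top + self.z_bottom)

    @property
    def thickness(self) -> float:
        return self.z_bottom - self.z_top


@dataclass(frozen=True)
class LungState:
    """Ordered apex-to-base stack of layers partitioning [0, height]."""

    height: float
    layers: tuple[Layer, ...]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("lung needs at least one layer")
        if abs(self.layers[0].z_top) > 1e-9 or abs(self.layers[-1].z_bottom - self.height) > 1e-9:
            raise ValueError("layers must span [0, height]")
        for upper, lower in zip(self.layers, self.layers[1:]):
            if abs(upper.z_bottom - lower.z_top) > 1e-9:
                raise ValueError("layers must partition the height with no gaps or overlaps")

    @property
    def n_total(self) -> float:
        return math.fsum(layer.n_alveoli for layer in self.layers)


@dataclass(frozen=True)
class InflationDeflationPressures:
    """Apical transpulmonary pressures at full inflation (TLC) and full
    deflation (RV), sharing one hydrostatic gradient."""

    p_tlc_apex: float
    p_rv_apex: float
    rho_frac: float = 0.25

    def __post_init__(self) -> None:
        if not self.p_tlc_apex > self.p_rv_apex:
            raise ValueError("full inflation must sit at higher apical Ptp than full deflation")

    def inflation_profile(self, height: float) -> PressureProfile:
        return PressureProfile(self.p_tlc_apex, height, self.rho_frac)

    def deflation_profile(self, height: float) -> PressureProfile:
        return PressureProfile(self.p_rv_apex, height, self.rho_frac)


@dataclass(frozen=True)
class RegionalProfile:
    """Per-layer volumes and RV/TLC ratios at layer midpoints."""

    z_from_apex: np.ndarray
    z_from_base: np.ndarray
    n_alveoli: np.ndarray
    v_tlc: np.ndarray
    v_rv: np.ndarray
    rv_tlc: np.ndarray
    closure_depth: float | Closure

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z_from_apex_cm": self.z_from_apex,
                "z_from_base_cm": self.z_from_base,
                "n_alveoli": self.n_alveoli,
                "v_tlc_ul": self.v_tlc,
                "v_rv_ul": self.v_rv,
                "rv_tlc": self.rv_tlc,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, columns=PROFILE_COLUMNS, lineterminator="\n")


def _closure_to_json(value: float | Closure):
    return value.value if isinstance(value, Closure) else value


@dataclass(frozen=True)
class LungSummary:
    """Integrated whole-lung volumes (liters) for one scenario."""

    tlc: float
    rv: float
    rv_tlc: float
    closure_depth: float | Closure
    p_tlc_apex: float

    def to_dict(self) -> dict:
        return {
            "tlc_l": self.tlc,
            "rv_l": self.rv,
            "rv_tlc": self.rv_tlc,
            "closure_depth_cm": _closure_to_json(self.closure_depth),
            "p_tlc_apex_cmh2o": self.p_tlc_apex,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def build_uniform_lung(
    height: float, n_total: float, params: AlveolarParams, n_layers: int = DEFAULT_N_LAYERS
) -> LungState:
    """Equal-thickness layers with alveoli apportioned uniformly.

    Counts are apportioned proportionally to thickness and rounded by the
    largest-remainder rule so the layer counts sum to ``n_total`` exactly.
    """
    if not height > 0:
        raise ValueError("height must be positive")
    if n_layers < 1:
        raise ValueError("need at least one layer")
    if n_total < 0:
        raise ValueError("n_total must be >= 0")
    edges = np.linspace(0.0, height, n_layers + 1)
    share = n_total / n_layers
    floors = np.full(n_layers, np.floor(share))
    remainder = int(round(n_total - floors.sum()))
    order = np.argsort(-(np.full(n_layers, share) - floors), kind="stable")
    counts = floors.copy()
    counts[order[:remainder]] += 1
    layers = tuple(
        Layer(float(edges[i]), float(edges[i + 1]), float(counts[i]), params)
        for i in range(n_layers)
    )
    return LungState(height=height, layers=layers)


def regional_profile(
    lung: LungState, pressures: InflationDeflationPressures, rule: ClosureRule
) -> RegionalProfile:
    """Per-layer TLC and RV volumes and their ratio, at layer midpoints.

    Closure applies on the deflation limb only: a layer whose midpoint lies
    at or below the closure depth holds the trapped-gas volume V(Ptm').
    Full inflation is required to keep every airway open; a scenario whose
    inflation-limb Ptp drops to Ptm' anywhere raises
    :class:`InflationClosureError` rather than silently trapping gas at TLC.
    """
    mids = np.array([layer.midpoint for layer in lung.layers])
    counts = np.array([layer.n_alveoli for layer in lung.layers])
    infl = pressures.inflation_profile(lung.height)
    defl = pressures.deflation_profile(lung.height)
    if infl.p_base <= rule.p_tm:
        raise InflationClosureError(
            f"inflation limb reaches Ptp={infl.p_base:.3f} <= Ptm'={rule.p_tm:.3f} at the base"
        )
    zstar = closure_depth(defl, rule)
    if zstar is Closure.NONE:
        closed = np.zeros(mids.shape, dtype=bool)
    elif zstar is Closure.ALL:
        closed = np.ones(mids.shape, dtype=bool)
    else:
        closed = mids >= zstar

    ptp_infl = ptp_at_depth(infl, mids)
    ptp_defl = np.where(closed, rule.p_tm, ptp_at_depth(defl, mids))
    v_tlc = np.empty_like(mids)
    v_rv = np.empty_like(mids)
    for i, layer in enumerate(lung.layers):
        v_tlc[i] = alveolar_volume(layer.params, ptp_infl[i])
        v_rv[i] = alveolar_volume(layer.params, ptp_defl[i])
    return RegionalProfile(
        z_from_apex=mids,
        z_from_base=lung.height - mids,
        n_alveoli=counts,
        v_tlc=v_tlc,
        v_rv=v_rv,
        rv_tlc=v_rv / v_tlc,
        closure_depth=zstar,
    )


def lung_summary(
    lung: LungState, profile: RegionalProfile, p_tlc_apex: float | None = None
) -> LungSummary:
    """Whole-lung TLC, RV and RV/TLC by integrating over all alveoli."""
    n = profile.n_alveoli
    if n.sum() <= 0:
        raise ZeroDivisionError("cannot summarize an empty lung")
    tlc_l = float(n @ profile.v_tlc) * 1e-6
    rv_l = float(n @ profile.v_rv) * 1e-6
    return LungSummary(
        tlc=tlc_l,
        rv=rv_l,
        rv_tlc=rv_l / tlc_l,
        closure_depth=profile.closure_depth,
        p_tlc_apex=p_tlc_apex if p_tlc_apex is not None else float("nan"),
    )


def _segment_mean(params: AlveolarParams, p_apex: float, c: float, z_lo: float, z_hi: float) -> float:
    # mean of V(p_apex - c z) over [z_lo, z_hi]; c = 0 reduces to V(p_apex)
    if z_hi <= z_lo:
        raise ValueError("need z_hi > z_lo")
    if c == 0:
        return alveolar_volume(params, p_apex)
    k = params.k
    width = z_hi - z_lo
    integral_exp = (
        math.exp(-k * p_apex) * (math.exp(k * c * z_hi) - math.exp(k * c * z_lo)) / (k * c)
    )
    return params.v_max - params.a * integral_exp / width


def closed_form_totals(
    height: float,
    params: AlveolarParams,
    pressures: InflationDeflationPressures,
    rule: ClosureRule,
) -> tuple[float, float]:
    """Analytic per-alveolus mean TLC and RV volumes for a uniform lung.

    Integrates ``V(Ptp(z))`` exactly over [0, height], splitting the
    deflation limb at the closure depth where the integrand becomes the
    constant trapped volume V(Ptm'). Serves as the quadrature oracle for
    the discretized layer sums.
    """
    c = pressures.rho_frac
    tlc_mean = _segment_mean(params, pressures.p_tlc_apex, c, 0.0, height)
    defl = pressures.deflation_profile(height)
    zstar = closure_depth(defl, rule)
    trapped = alveolar_volume(params, rule.p_tm)
    if zstar is Closure.NONE:
        rv_mean = _segment_mean(params, pressures.p_rv_apex, c, 0.0, height)
    elif zstar is Closure.ALL:
        rv_mean = trapped
    else:
        open_part = _segment_mean(params, pressures.p_rv_apex, c, 0.0, zstar) * zstar
        rv_mean = (open_part + trapped * (height - zstar)) / height
    return tlc_mean, rv_mean
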