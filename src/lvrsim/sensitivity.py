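"""Parameter sensitivity sweeps and the ULT-dominance scan.

The sweep varies the four parameters that define disease severity — the
alveolar count ``n``, the shape factor ``k``, the trapping ratio
``Vmin/Vmax`` and the closing pressure ``Ptm'`` — by a relative span
(default ±25%) around a base scenario, either one at a time or jointly on
a full factorial grid. Every grid point is a complete deterministic
simulation; invalid combinations (e.g. a trapping ratio reaching 1) are
recorded as error rows rather than dropped.

The dominance scan pairs an upper-lobe and a lower-lobe treatment arm
with identical removal counts at every grid point and reports the
fraction of the grid where upper-lobe treatment reduces whole-lung RV/TLC
at least as much as lower-lobe treatment (ties count as dominance).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import AlveolarParams
from .scenarios import ScenarioSpec, TreatmentSpec, compare_ult_llt

__all__ = ["SweepSpec", "run_sweep", "DominanceResult", "dominance_scan", "SWEEP_PARAMETERS"]

SWEEP_PARAMETERS = ("n", "k", "vmin_vmax", "p_tm")


@dataclass(frozen=True)
class SweepSpec:
    base: ScenarioSpec
    parameters: tuple[str, ...] = SWEEP_PARAMETERS
    span: float = 0.25
    points: int = 3
    mode: str = "one_at_a_time"  # or "joint"

    def __post_init__(self) -> None:
        unknown = set(self.parameters) - set(SWEEP_PARAMETERS)
        if unknown:
            raise ValueError(f"unknown sweep parameters {sorted(unknown)}")
        if not self.parameters:
            raise ValueError("sweep needs at least one parameter")
        if self.span < 0:
            raise ValueError("span must be >= 0")
        if self.points < 2:
            raise ValueError("need at least 2 grid points per axis")
        if self.mode not in ("one_at_a_time", "joint"):
            raise ValueError("mode must be 'one_at_a_time' or 'joint'")


def perturb_scenario(base: ScenarioSpec, factors: dict[str, float]) -> ScenarioSpec:
    """Scenario with named parameters multiplied by relative factors.

    ``vmin_vmax`` scales the trapping ratio at fixed Vmax; the resulting
    ratio must stay below 1 (raises ``ValueError`` otherwise, which sweep
    drivers record as an error row).
    """
    params = base.params
    if "vmin_vmax" in factors:
        ratio = params.ratio * factors["vmin_vmax"]
        if ratio >= 1:
            raise ValueError(f"Vmin/Vmax reaches {ratio:.3f} >= 1")
        params = AlveolarParams(params.v_max, params.v_max * ratio, params.k)
    if "k" in factors:
        params = AlveolarParams(params.v_max, params.v_min, params.k * factors["k"])
    out = replace(base, params=params)
    if "n" in factors:
        out = replace(out, n_total=base.n_total * factors["n"])
    if "p_tm" in factors:
        out = replace(out, p_tm=base.p_tm * factors["p_tm"])
    return out


def _factor_grid(spec: SweepSpec):
    levels = np.linspace(1.0 - spec.span, 1.0 + spec.span, spec.points)
    if spec.mode == "joint":
        for combo in itertools.product(levels, repeat=len(spec.parameters)):
            yield dict(zip(spec.parameters, (float(c) for c in combo)))
    else:
        for name in spec.parameters:
            for level in levels:
                yield {name: float(level)}


def _base_factors(spec: SweepSpec) -> dict[str, float]:
    return {name: 1.0 for name in spec.parameters}


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Evaluate the sweep grid; one fully-simulated row per grid point.

    Columns: a ``factor_<name>`` column per swept parameter, the realized
    parameter values, whole-lung ``rv_tlc``/``tlc_l``/``rv_l``, the closure
    depth, the regional RV/TLC extrema, and an ``error`` column (empty
    string for valid rows).
    """
    rows = []
    for point in _factor_grid(spec):
        factors = _base_factors(spec) | point
        row = {f"factor_{name}": factors[name] for name in spec.parameters}
        try:
            scenario = perturb_scenario(spec.base, factors)
            result = scenario.run()
            summary, profile = result.summary, result.profile
            zstar = summary.closure_depth
            row.update(
                n=scenario.n_total,
                k=scenario.params.k,
                vmin_vmax=scenario.params.ratio,
                p_tm=scenario.p_tm,
                rv_tlc=summary.rv_tlc,
                tlc_l=summary.tlc,
                rv_l=summary.rv,
                closure_depth_cm=zstar if isinstance(zstar, float) else np.nan,
                rv_tlc_regional_min=float(profile.rv_tlc.min()),
                rv_tlc_regional_max=float(profile.rv_tlc.max()),
                error="",
            )
        except ValueError as exc:
            row.update(error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DominanceResult:
    """Outcome of the paired ULT-vs-LLT grid scan."""

    fraction: float
    table: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "dominance_fraction": self.fraction,
            "n_grid_points": int(len(self.table)),
            "n_valid": int((self.table["error"] == "").sum()),
        }


def dominance_scan(
    base: ScenarioSpec,
    ult: TreatmentSpec,
    llt: TreatmentSpec,
    parameters: tuple[str, ...] = SWEEP_PARAMETERS,
    span: float = 0.25,
    points: int = 3,
    recalibrate: bool = False,
) -> DominanceResult:
    """Fraction of a joint parameter grid where ULT is at least as
    effective as LLT at reducing whole-lung RV/TLC.

    At each grid point the base scenario is perturbed with the calibrated
    pressures held fixed, the identical paired treatments are applied, and
    the percent changes in whole-lung RV/TLC compared. Ties count as
    dominance. With ``recalibrate`` the deflation pressure is instead
    re-anchored per point to the base scenario's own RV/TLC (representing
    patients sharing the same baseline trapping); grid points whose
    attainable range excludes the anchor are recorded as error rows.
    """
    from .calibration import calibrate_scenario

    if ult.n_removed != llt.n_removed:
        raise ValueError("paired treatments must remove equal counts")
    anchor = base.run().summary.rv_tlc if recalibrate else None
    spec = SweepSpec(base, parameters, span, points, mode="joint")
    rows = []
    for point in _factor_grid(spec):
        factors = _base_factors(spec) | point
        row = {f"factor_{name}": factors[name] for name in parameters}
        try:
            scenario = perturb_scenario(base, factors)
            if anchor is not None:
                scenario = calibrate_scenario(scenario, rv_tlc=anchor)
            comparison = compare_ult_llt(scenario, ult, llt)
            d_ult = comparison.delta_rv_tlc_percent["ult"]
            d_llt = comparison.delta_rv_tlc_percent["llt"]
            row.update(
                baseline_rv_tlc=comparison.baseline.rv_tlc,
                delta_ult_percent=d_ult,
                delta_llt_percent=d_llt,
                ult_dominates=bool(d_ult <= d_llt + 1e-9),
                error="",
            )
        except ValueError as exc:
            row.update(error=str(exc))
        rows.append(row)
    table = pd.DataFrame(rows)
    valid = table[table["error"] == ""]
    fraction = float(valid["ult_dominates"].mean()) if len(valid) else float("nan")
    return DominanceResult(fraction=fraction, table=table)
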