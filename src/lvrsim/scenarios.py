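"""Named scenarios and the volume-reduction treatment transform.

Two presets bracket the physiology:

* ``healthy_preset`` — 300 million alveoli, Vmax 20 µL, Vmin 4 µL, k 0.2,
  Ptm' 0, apex-to-base height 35 cm. Apical Ptp is 30 cm H2O at full
  inflation; the full-deflation apical pressure is set so that airway
  closure sits exactly at the lung base (Ptm' = 0 there).
* ``emphysema_preset`` — severe homogeneous emphysema: half the alveoli
  (150 million), Vmin/Vmax raised to 0.5, k raised to 0.3, Ptm' raised to
  1 cm H2O, recoil at full inflation reduced to 12.5 cm H2O. The two free
  degrees of freedom the physiology does not pin down — the deflation-limb
  apical pressure and the absolute alveolar volume scale — are resolved by
  calibrating whole-lung RV/TLC to 0.68 and RV to 5.8 L.

Volume reduction therapy eliminates alveoli in a target region, shortens
the lung, raises transpulmonary pressure across the volume range
(restored recoil), and lowers the airway closing pressure (restored
tethering). The treatment transform applies exactly those four shifts and
nothing else: the constitutive parameters of surviving alveoli are
untouched, so post-treatment volumes are genuine predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .assembly import (
    DEFAULT_N_LAYERS,
    InflationDeflationPressures,
    Layer,
    LungState,
    LungSummary,
    RegionalProfile,
    build_uniform_lung,
    lung_summary,
    regional_profile,
)
from .core import AlveolarParams, ClosureRule

__all__ = [
    "ScenarioSpec",
    "TreatmentSpec",
    "SimulationResult",
    "ComparisonResult",
    "InvalidTreatmentError",
    "InvalidComparisonError",
    "healthy_preset",
    "emphysema_preset",
    "ult_treatment",
    "llt_treatment",
    "apply_treatment",
    "compare_ult_llt",
    "heterogeneity_index",
    "EMPHYSEMA_RV_TLC_ANCHOR",
    "EMPHYSEMA_RV_LITERS_ANCHOR",
]

#: Published whole-lung anchors of the severe homogeneous emphysema scenario.
EMPHYSEMA_RV_TLC_ANCHOR = 0.68
EMPHYSEMA_RV_LITERS_ANCHOR = 5.8

#: Inclusive CT Heterogeneity Index band classifying disease as homogeneous.
HOMOGENEOUS_HI_BAND = (0.85, 1.15)


class InvalidTreatmentError(ValueError):
    """Treatment specification inconsistent with the lung it targets."""


class InvalidComparisonError(ValueError):
    """Paired treatment arms that are not comparable."""


@dataclass(frozen=True)
class SimulationResult:
    state: LungState
    profile: RegionalProfile
    summary: LungSummary


@dataclass(frozen=True)
class ScenarioSpec:
    """Everything needed to build and run one static lung simulation."""

    name: str
    height: float
    n_total: float
    params: AlveolarParams
    p_tlc_apex: float
    p_rv_apex: float | None
    p_tm: float
    rho_frac: float = 0.25
    n_layers: int = DEFAULT_N_LAYERS

    @property
    def rule(self) -> ClosureRule:
        return ClosureRule(self.p_tm)

    @property
    def pressures(self) -> InflationDeflationPressures:
        if self.p_rv_apex is None:
            raise ValueError(
                f"scenario {self.name!r} has no deflation apical pressure; calibrate it first"
            )
        return InflationDeflationPressures(self.p_tlc_apex, self.p_rv_apex, self.rho_frac)

    def build_state(self) -> LungState:
        return build_uniform_lung(self.height, self.n_total, self.params, self.n_layers)

    def run(self) -> SimulationResult:
        state = self.build_state()
        profile = regional_profile(state, self.pressures, self.rule)
        summary = lung_summary(state, profile, p_tlc_apex=self.p_tlc_apex)
        return SimulationResult(state, profile, summary)

    def with_scale(self, factor: float) -> "ScenarioSpec":
        return replace(self, params=self.params.scaled(factor))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "height_cm": self.height,
            "n_total": self.n_total,
            "v_max_ul": self.params.v_max,
            "v_min_ul": self.params.v_min,
            "k_per_cmh2o": self.params.k,
            "p_tlc_apex_cmh2o": self.p_tlc_apex,
            "p_rv_apex_cmh2o": self.p_rv_apex,
            "p_tm_cmh2o": self.p_tm,
            "rho_frac": self.rho_frac,
            "n_layers": self.n_layers,
        }


@dataclass(frozen=True)
class TreatmentSpec:
    """Volume-reduction transform applied to a baseline lung.

    ``region`` is the depth interval [z_lo, z_hi) (cm from apex, baseline
    grid) from which ``n_removed`` alveoli are eliminated, spread
    proportionally over the layer populations inside it. The lung shortens
    to ``height_post`` (uniform affine rescale of the layer grid), the
    apical Ptp at full inflation rises to ``p_tlc_apex_post``, and the
    closing pressure drops to ``p_tm_post``. ``p_rv_apex_post`` sets the
    deflation-limb apical Ptp; by default the recoil gain is applied to the
    whole Ptp field, i.e. the deflation limb shifts by the same increment
    as the inflation limb.
    """

    region: tuple[float, float]
    n_removed: float
    p_tlc_apex_post: float
    p_tm_post: float
    height_post: float
    p_rv_apex_post: float | None = None

    def __post_init__(self) -> None:
        z_lo, z_hi = self.region
        if not (0 <= z_lo < z_hi):
            raise ValueError(f"invalid target region {self.region}")
        if self.n_removed < 0:
            raise ValueError("n_removed must be >= 0")


def healthy_preset(n_layers: int = DEFAULT_N_LAYERS) -> ScenarioSpec:
    """Healthy adult lung: n=300e6, Vmax=20 µL, Vmin=4 µL, k=0.2, Ptm'=0."""
    height, rho_frac, p_tm = 35.0, 0.25, 0.0
    return ScenarioSpec(
        name="healthy",
        height=height,
        n_total=300e6,
        params=AlveolarParams(v_max=20.0, v_min=4.0, k=0.2),
        p_tlc_apex=30.0,
        # closure exactly at the base on the deflation limb: Ptp(height) = Ptm'
        p_rv_apex=p_tm + rho_frac * height,
        p_tm=p_tm,
        rho_frac=rho_frac,
        n_layers=n_layers,
    )


def emphysema_preset(calibrated: bool = True, n_layers: int = DEFAULT_N_LAYERS) -> ScenarioSpec:
    """Severe homogeneous emphysema: n=150e6, Vmin/Vmax=0.5, k=0.3, Ptm'=1.

    Recoil at full inflation is 12.5 cm H2O. With ``calibrated=True`` the
    deflation apical pressure and the absolute volume scale are resolved
    against the whole-lung anchors RV/TLC = 0.68 and RV = 5.8 L; with
    ``calibrated=False`` the deflation pressure is left unset and the
    nominal volume scale (Vmax 40 µL, double the healthy alveolus) is kept.
    """
    spec = ScenarioSpec(
        name="emphysema",
        height=35.0,
        n_total=150e6,
        params=AlveolarParams(v_max=40.0, v_min=20.0, k=0.3),
        p_tlc_apex=12.5,
        p_rv_apex=None,
        p_tm=1.0,
        rho_frac=0.25,
        n_layers=n_layers,
    )
    if not calibrated:
        return spec
    from .calibration import calibrate_scenario

    return calibrate_scenario(
        spec, rv_tlc=EMPHYSEMA_RV_TLC_ANCHOR, rv_liters=EMPHYSEMA_RV_LITERS_ANCHOR
    )


def _published_transform(base: ScenarioSpec) -> dict:
    return {
        "n_removed": 22e6,
        "p_tlc_apex_post": base.p_tlc_apex + 1.5,
        "p_tm_post": base.p_tm - 0.5,
        "height_post": base.height - 2.0,
    }


def ult_treatment(base: ScenarioSpec, upper_fraction: float = 0.5, **overrides) -> TreatmentSpec:
    """Upper-lobe volume reduction: the published transform (remove 22e6
    alveoli, recoil 12.5→14 cm H2O, Ptm' 1→0.5, height 35→33 cm) targeted
    at the apical ``upper_fraction`` of lung height."""
    kwargs = _published_transform(base) | overrides
    return TreatmentSpec(region=(0.0, base.height * upper_fraction), **kwargs)


def llt_treatment(base: ScenarioSpec, lower_fraction: float = 0.5, **overrides) -> TreatmentSpec:
    """Lower-lobe counterpart of :func:`ult_treatment`: the same transform
    targeted at the basal ``lower_fraction`` of lung height."""
    kwargs = _published_transform(base) | overrides
    return TreatmentSpec(region=(base.height * (1.0 - lower_fraction), base.height), **kwargs)


def _region_population(lung: LungState, region: tuple[float, float]) -> list[float]:
    z_lo, z_hi = region
    in_region = []
    for layer in lung.layers:
        overlap = max(0.0, min(layer.z_bottom, z_hi) - max(layer.z_top, z_lo))
        in_region.append(layer.n_alveoli * overlap / layer.thickness)
    return in_region


def apply_treatment(
    lung: LungState,
    pressures: InflationDeflationPressures,
    rule: ClosureRule,
    spec: TreatmentSpec,
) -> tuple[LungState, InflationDeflationPressures, ClosureRule]:
    """Apply a volume-reduction transform; returns the post-treatment lung,
    pressures and closure rule. Constitutive parameters of surviving
    alveoli are left unchanged."""
    if spec.height_post > lung.height:
        raise InvalidTreatmentError("volume reduction cannot lengthen the lung")
    if spec.p_tlc_apex_post < pressures.p_tlc_apex:
        raise InvalidTreatmentError("volume reduction cannot lower recoil at full inflation")
    if spec.p_tm_post > rule.p_tm:
        raise InvalidTreatmentError("volume reduction cannot raise the closing pressure")
    in_region = _region_population(lung, spec.region)
    region_total = math.fsum(in_region)
    if spec.n_removed > region_total * (1 + 1e-12):
        raise InvalidTreatmentError(
            f"cannot remove {spec.n_removed:g} alveoli from a region holding {region_total:g}"
        )
    frac = 0.0 if spec.n_removed == 0 else spec.n_removed / region_total
    scale = spec.height_post / lung.height
    new_layers = tuple(
        Layer(
            layer.z_top * scale,
            layer.z_bottom * scale,
            layer.n_alveoli - frac * in_region[i],
            layer.params,
        )
        for i, layer in enumerate(lung.layers)
    )
    p_rv_post = (
        spec.p_rv_apex_post
        if spec.p_rv_apex_post is not None
        else pressures.p_rv_apex + (spec.p_tlc_apex_post - pressures.p_tlc_apex)
    )
    return (
        LungState(height=spec.height_post, layers=new_layers),
        InflationDeflationPressures(spec.p_tlc_apex_post, p_rv_post, pressures.rho_frac),
        ClosureRule(spec.p_tm_post),
    )


def run_treated(base: ScenarioSpec, treatment: TreatmentSpec) -> SimulationResult:
    """Simulate ``base`` after applying ``treatment``."""
    state, pressures, rule = apply_treatment(
        base.build_state(), base.pressures, base.rule, treatment
    )
    profile = regional_profile(state, pressures, rule)
    summary = lung_summary(state, profile, p_tlc_apex=pressures.p_tlc_apex)
    return SimulationResult(state, profile, summary)


@dataclass(frozen=True)
class ComparisonResult:
    """Head-to-head ULT vs LLT run from a shared baseline."""

    baseline: LungSummary
    post_ult: LungSummary
    post_llt: LungSummary
    delta_rv_tlc_percent: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "baseline": self.baseline.to_dict(),
            "post_ult": self.post_ult.to_dict(),
            "post_llt": self.post_llt.to_dict(),
            "delta_rv_tlc_percent": dict(self.delta_rv_tlc_percent),
        }


def compare_ult_llt(
    base: ScenarioSpec, ult: TreatmentSpec, llt: TreatmentSpec
) -> ComparisonResult:
    """Run baseline, upper-lobe and lower-lobe arms with matched transforms.

    The arms must eliminate the same number of alveoli and share identical
    pressure/height shifts, so any outcome difference is attributable to
    the treatment site alone.
    """
    if ult.n_removed != llt.n_removed:
        raise InvalidComparisonError("arms must remove the same number of alveoli")
    shared = ("p_tlc_apex_post", "p_tm_post", "height_post", "p_rv_apex_post")
    for attr in shared:
        if getattr(ult, attr) != getattr(llt, attr):
            raise InvalidComparisonError(f"arms must share {attr}")
    baseline = base.run().summary
    post_ult = run_treated(base, ult).summary
    post_llt = run_treated(base, llt).summary
    deltas = {
        "ult": 100.0 * (post_ult.rv_tlc - baseline.rv_tlc) / baseline.rv_tlc,
        "llt": 100.0 * (post_llt.rv_tlc - baseline.rv_tlc) / baseline.rv_tlc,
    }
    return ComparisonResult(baseline, post_ult, post_llt, deltas)


def heterogeneity_index(upper_frac: float, lower_frac: float) -> tuple[float, bool]:
    """CT Heterogeneity Index: ratio of the low-attenuation (< −910 HU)
    voxel fraction in the upper lobes to that in the lower lobes.

    Disease is classified homogeneous when HI lies in [0.85, 1.15]
    (inclusive). Both fractions must lie in (0, 1].
    """
    for label, value in (("upper_frac", upper_frac), ("lower_frac", lower_frac)):
        if not (0 < value <= 1):
            raise ValueError(f"{label} must lie in (0, 1], got {value}")
    hi = upper_frac / lower_frac
    lo, hi_bound = HOMOGENEOUS_HI_BAND
    return hi, lo <= hi <= hi_bound
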