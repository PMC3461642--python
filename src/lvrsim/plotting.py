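"""Optional figure output: regional RV/TLC curves and sweep envelopes.

Plots mirror the field's convention of RV/TLC on the ordinate against
distance from the lung base on the abscissa. Matplotlib is used with the
Agg backend; plotting is cosmetic and never load-bearing.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .assembly import RegionalProfile
from .sensitivity import SweepSpec, _base_factors, _factor_grid, perturb_scenario

__all__ = ["plot_regional_profiles", "plot_sweep_envelope"]


def plot_regional_profiles(profiles: dict[str, RegionalProfile], path) -> None:
    """Overlay regional RV/TLC vs distance-from-base for named profiles."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, profile in profiles.items():
        ax.plot(profile.z_from_base, profile.rv_tlc, label=label)
    ax.set_xlabel("distance from lung base (cm)")
    ax.set_ylabel("regional RV/TLC")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_sweep_envelope(spec: SweepSpec, path) -> None:
    """Regional RV/TLC curves for every sweep grid point plus the base.

    Invalid grid points are skipped; the base scenario is drawn bold.
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    for point in _factor_grid(spec):
        factors = _base_factors(spec) | point
        try:
            profile = perturb_scenario(spec.base, factors).run().profile
        except ValueError:
            continue
        ax.plot(profile.z_from_base, profile.rv_tlc, color="steelblue", alpha=0.4, lw=0.8)
    base_profile = spec.base.run().profile
    ax.plot(base_profile.z_from_base, base_profile.rv_tlc, color="black", lw=2, label="base")
    ax.set_xlabel("distance from lung base (cm)")
    ax.set_ylabel("regional RV/TLC")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
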