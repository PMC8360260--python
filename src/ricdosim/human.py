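"""Interspecies dose projection by the %kg/g method.

Human source-organ activity fractions are extrapolated from mouse data by

    (%ID/organ)_human = (%ID/organ)_mouse × (mouse BW / human BW)

with the sampling time points kept unchanged (no allometric time
scaling).  The projected %ID/organ time courses are integrated with the
same AUC + decay-tail rules as the mouse analysis and dosed with a
human-phantom S-value table; the tumour is dosed via the sphere model,
by default a 2 cm diameter unit-density sphere (4.19 g).

Because every step is linear, the projected human Ã of each organ equals
(BW ratio) × the mouse organ Ã on the same time grid — the implementation
exploits this identity directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .biodist import BiodistMeasurement, summarize
from .dose import DoseReport, SphereSValueCurve, SValueTable, sphere_mass_from_diameter_cm
from .errors import ValidationError
from .nuclides import Nuclide
from .pipeline import dose_report, resolve_mass

DEFAULT_HUMAN_TUMOUR_MASS_G = sphere_mass_from_diameter_cm(2.0)  # ≈ 4.19 g


@dataclass(frozen=True)
class SpeciesScaling:
    """Body weights for the %kg/g extrapolation (defaults: 30 g mouse,
    56,900 g adult female human)."""

    mouse_body_weight_g: float = 30.0
    human_body_weight_g: float = 56_900.0

    def __post_init__(self):
        if not (self.mouse_body_weight_g > 0 and self.human_body_weight_g > 0):
            raise ValidationError("body weights must be > 0")

    @property
    def ratio(self) -> float:
        return self.mouse_body_weight_g / self.human_body_weight_g


def project_pct_id_organ(pct_id_organ_mouse: float, scaling: SpeciesScaling) -> float:
    """Human %ID/organ from mouse %ID/organ (note: whole-organ percent,
    not %ID/g)."""
    if pct_id_organ_mouse < 0 or not math.isfinite(pct_id_organ_mouse):
        raise ValidationError(f"%ID/organ must be ≥ 0, got {pct_id_organ_mouse}")
    return pct_id_organ_mouse * scaling.ratio


def projected_human_pct_id_table(
    measurements: Sequence[BiodistMeasurement],
    organ_masses: Mapping[str, float] | None,
    scaling: SpeciesScaling,
) -> pd.DataFrame:
    """Audit table: mouse and projected human %ID/organ per organ × time."""
    rows = []
    for s in summarize(measurements):
        mass = resolve_mass(measurements, s.organ, organ_masses)
        mouse_pct = s.mean_pct_id_per_g * mass
        rows.append(
            {
                "organ": s.organ,
                "time_h": s.time_h,
                "mouse_pct_id_per_organ": mouse_pct,
                "human_pct_id_per_organ": project_pct_id_organ(mouse_pct, scaling),
            }
        )
    return pd.DataFrame(rows)


def project_human_doses(
    measurements: Sequence[BiodistMeasurement],
    nuclide: Nuclide,
    human_s_table: SValueTable,
    organ_masses: Mapping[str, float] | None = None,
    sphere_curve: SphereSValueCurve | None = None,
    scaling: SpeciesScaling = SpeciesScaling(),
    injected_MBq: float = 1.0,
    tumour_mass_g: float = DEFAULT_HUMAN_TUMOUR_MASS_G,
    T_h: float = 48.0,
    boundary_rule: str = "plateau",
    w_r: float = 1.0,
    whole_body_mode: str = "sum_of_sources",
    apply_decay: bool = True,
):
    """Projected human dose report from a mouse biodistribution table.

    The %kg/g projection scales every organ's Ã by the body-weight ratio
    (time points unchanged), so the computation runs the mouse pipeline
    with ``scale_tia = ratio`` and the human S-value table.  The tumour
    time course is projected like an organ (converted at the mouse tumour
    mass) but its sphere S-value is evaluated at ``tumour_mass_g``
    (default 2 cm unit-density sphere, 4.19 g).  Doses are reported in
    Sv; use ``report.doses_mSv_per_MBq`` for the conventional human
    units.
    """
    return dose_report(
        measurements,
        nuclide,
        injected_MBq,
        human_s_table,
        organ_masses=organ_masses,
        sphere_curve=sphere_curve,
        tumour_s_mass_g=tumour_mass_g,
        T_h=T_h,
        boundary_rule=boundary_rule,
        w_r=w_r,
        whole_body_mode=whole_body_mode,
        apply_decay=apply_decay,
        scale_tia=scaling.ratio,
    )
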