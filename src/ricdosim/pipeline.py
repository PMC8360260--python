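"""End-to-end assembly: biodistribution table → TIAs → dose report.

This is the glue the CLI and the human-projection module share.  Organ
masses come from per-row ``organ_mass_g`` values when present, otherwise
from the organ-mass registry; the tumour is dosed exclusively through
the sphere self-dose model at its measured mass, and the whole body
either from a measured whole_body row or as the sum of organ sources.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np

from .biodist import BiodistMeasurement
from .dose import (
    DoseReport,
    SphereSValueCurve,
    SValueTable,
    equivalent_dose,
    sphere_s_value,
    whole_body_tia,
)
from .errors import MissingDataError
from .nuclides import Nuclide, hours_to_seconds
from .timeactivity import TimeIntegratedActivity, time_integrated_activity


def resolve_mass(
    measurements: Sequence[BiodistMeasurement],
    organ: str,
    organ_masses: Mapping[str, float] | None,
) -> float:
    """Organ mass: mean of per-row values if recorded, else the registry."""
    vals = [m.organ_mass_g for m in measurements if m.organ == organ and m.organ_mass_g]
    if vals:
        return float(np.mean(vals))
    if organ_masses and organ in organ_masses:
        return float(organ_masses[organ])
    raise MissingDataError(
        f"no mass for organ {organ!r}: supply organ_mass_g rows or a registry entry"
    )


def compute_tias(
    measurements: Sequence[BiodistMeasurement],
    nuclide: Nuclide,
    injected_Bq: float,
    organ_masses: Mapping[str, float] | None,
    T_h: float = 48.0,
    boundary_rule: str = "plateau",
    apply_decay: bool = True,
    organs: Sequence[str] | None = None,
) -> list[TimeIntegratedActivity]:
    """Per-organ time-integrated activities from group-mean %ID/g curves."""
    present = sorted({m.organ for m in measurements})
    organs = list(organs) if organs is not None else present
    T_s = hours_to_seconds(T_h)
    return [
        time_integrated_activity(
            measurements, organ, nuclide, injected_Bq,
            resolve_mass(measurements, organ, organ_masses),
            T_s, boundary_rule, apply_decay,
        )
        for organ in organs
    ]


def dose_report(
    measurements: Sequence[BiodistMeasurement],
    nuclide: Nuclide,
    injected_MBq: float,
    s_table: SValueTable,
    organ_masses: Mapping[str, float] | None = None,
    sphere_curve: SphereSValueCurve | None = None,
    tumour_mass_g: float | None = None,
    tumour_s_mass_g: float | None = None,
    T_h: float = 48.0,
    boundary_rule: str = "plateau",
    w_r: float = 1.0,
    whole_body_mode: str = "sum_of_sources",
    apply_decay: bool = True,
    scale_tia: float = 1.0,
) -> tuple[list[TimeIntegratedActivity], DoseReport]:
    """Full mouse-side dose report.

    Normal organs are dosed through ``s_table``; the tumour, when present
    and a sphere curve is supplied, exclusively through the sphere model.
    ``tumour_mass_g`` is the mass used to convert tumour %ID/g to whole-
    tumour activity (default: its resolved mass); ``tumour_s_mass_g`` is
    the mass at which the sphere S-value is evaluated (default: the same),
    kept separate so interspecies projection can dose a human-sized
    tumour fed by the mouse-measured time course.  The whole body follows
    ``whole_body_mode``.  ``scale_tia`` multiplies every Ã (used by the
    %kg/g projection, which is linear in Ã).
    """
    injected_Bq = injected_MBq * 1e6
    present = {m.organ for m in measurements}
    organ_list = sorted(present - {"tumour", "whole_body"})
    tias = compute_tias(
        measurements, nuclide, injected_Bq, organ_masses, T_h,
        boundary_rule, apply_decay, organ_list,
    )
    if scale_tia != 1.0:
        tias = [
            TimeIntegratedActivity(
                t.organ, scale_tia * t.auc_0_T_Bq_s, scale_tia * t.tail_Bq_s, t.T_s
            )
            for t in tias
        ]
    report = equivalent_dose(tias, s_table, w_r, injected_MBq)
    doses = dict(report.doses_Sv)

    all_tias = list(tias)
    if "tumour" in present and sphere_curve is not None:
        mass = (
            tumour_mass_g
            if tumour_mass_g is not None
            else resolve_mass(measurements, "tumour", organ_masses)
        )
        t_tia = compute_tias(
            measurements, nuclide, injected_Bq, {"tumour": mass} | dict(organ_masses or {}),
            T_h, boundary_rule, apply_decay, ["tumour"],
        )[0]
        if scale_tia != 1.0:
            t_tia = TimeIntegratedActivity(
                "tumour", scale_tia * t_tia.auc_0_T_Bq_s, scale_tia * t_tia.tail_Bq_s, t_tia.T_s
            )
        s_mass = tumour_s_mass_g if tumour_s_mass_g is not None else mass
        doses["tumour"] = t_tia.total_Bq_s * sphere_s_value(s_mass, sphere_curve) * w_r
        all_tias.append(t_tia)

    wb_sources = all_tias
    if whole_body_mode == "measured_row":
        if "whole_body" not in present:
            raise MissingDataError("whole-body mode measured_row but no whole_body rows")
        wb_tia = compute_tias(
            measurements, nuclide, injected_Bq, organ_masses, T_h,
            boundary_rule, apply_decay, ["whole_body"],
        )[0]
        if scale_tia != 1.0:
            wb_tia = TimeIntegratedActivity(
                "whole_body", scale_tia * wb_tia.auc_0_T_Bq_s,
                scale_tia * wb_tia.tail_Bq_s, wb_tia.T_s,
            )
    else:
        wb_tia = whole_body_tia(wb_sources, mode="sum_of_sources")
    all_tias.append(wb_tia)
    s_wb = s_table.s("whole_body", "whole_body")
    if s_wb > 0:
        doses["whole_body"] = wb_tia.total_Bq_s * s_wb * w_r

    prov = dict(report.provenance)
    prov.update(
        {
            "nuclide": nuclide.name,
            "T_h": T_h,
            "boundary_rule": boundary_rule,
            "whole_body_mode": whole_body_mode,
            "apply_decay": apply_decay,
            "tia_scale": scale_tia,
        }
    )
    return all_tias, DoseReport(doses, injected_MBq, w_r, prov)
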