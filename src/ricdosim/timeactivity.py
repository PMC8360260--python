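"""Time–activity curves and time-integrated activity (Ã).

The source-region activity at each sampling time t is

    A(t) = %ID/g(t) × ID/100 × organ mass × exp(−λt)

with ID the injected activity in Bq and λ the physical decay constant
(%ID/g tables are assumed decay-corrected; pass ``apply_decay=False`` for
tables that already include physical decay).  Ã is the trapezoidal AUC
over [0, T] plus a pure-physical-decay tail A(T)/λ — i.e. biological
elimination is assumed to stop at the last observation, which is the
conservative convention for a 48-h terminal study.

The unobserved segment [0, t_first] is handled by a selectable boundary
rule: ``plateau`` (hold the first value back to t = 0, default —
conservative for blood-borne agents), ``zero`` (A(0) = 0), or ``linear``
(back-extrapolate the first two points, floored at 0).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .biodist import BiodistMeasurement, summarize
from .errors import MissingDataError, ValidationError
from .nuclides import Nuclide, hours_to_seconds

BOUNDARY_RULES = ("plateau", "zero", "linear")


@dataclass(frozen=True)
class TimeActivityCurve:
    organ: str
    nuclide: Nuclide
    points: tuple[tuple[float, float], ...]  # (t_s, activity_Bq), strictly increasing t
    injected_activity_Bq: float
    boundary_rule: str = "plateau"

    def __post_init__(self):
        if self.boundary_rule not in BOUNDARY_RULES:
            raise ValidationError(f"boundary_rule must be one of {BOUNDARY_RULES}")
        ts = [p[0] for p in self.points]
        if any(t2 <= t1 for t1, t2 in zip(ts, ts[1:])):
            raise ValidationError("curve times must be strictly increasing")
        if any(a < 0 for _, a in self.points):
            raise ValidationError("activities must be ≥ 0")


@dataclass(frozen=True)
class TimeIntegratedActivity:
    """Ã for one source region: AUC over [0, T] plus the decay tail."""

    organ: str
    auc_0_T_Bq_s: float
    tail_Bq_s: float
    T_s: float

    def __post_init__(self):
        if self.auc_0_T_Bq_s < 0 or self.tail_Bq_s < 0:
            raise ValidationError("Ã components must be ≥ 0")

    @property
    def total_Bq_s(self) -> float:
        return self.auc_0_T_Bq_s + self.tail_Bq_s


def activity_at(
    pct_id_per_g: float,
    injected_Bq: float,
    organ_mass_g: float,
    nuclide: Nuclide,
    t_s: float,
    apply_decay: bool = True,
) -> float:
    """Absolute source-organ activity in Bq at time t (seconds)."""
    if pct_id_per_g < 0 or injected_Bq < 0 or t_s < 0:
        raise ValidationError("pct_id_per_g, injected_Bq and t_s must be ≥ 0")
    if organ_mass_g is None:
        raise MissingDataError("organ mass is required to convert %ID/g to activity")
    if not (organ_mass_g > 0 and math.isfinite(organ_mass_g)):
        raise ValidationError(f"organ_mass_g must be > 0, got {organ_mass_g}")
    a = pct_id_per_g / 100.0 * injected_Bq * organ_mass_g
    if apply_decay:
        a *= math.exp(-nuclide.decay_constant * t_s)
    return a


def _boundary_point(points: Sequence[tuple[float, float]], rule: str) -> tuple[float, float]:
    t0, a0 = points[0]
    if t0 == 0.0:
        return (t0, a0)
    if rule == "plateau":
        return (0.0, a0)
    if rule == "zero":
        return (0.0, 0.0)
    # linear: back-extrapolate the first two points, floored at 0
    if len(points) < 2:
        return (0.0, a0)
    (t1, a1), (t2, a2) = points[0], points[1]
    slope = (a2 - a1) / (t2 - t1)
    return (0.0, max(a1 - slope * t1, 0.0))


def integrate_to_T(curve: TimeActivityCurve, T_s: float) -> float:
    """Trapezoidal AUC of the curve over [0, T] in Bq·s."""
    if not curve.points:
        raise ValidationError("curve has no points")
    ts = np.array([p[0] for p in curve.points])
    if T_s < ts[0]:
        raise ValidationError(f"T = {T_s} s precedes the first observation at {ts[0]} s")
    t0, a0 = _boundary_point(curve.points, curve.boundary_rule)
    pts = [(t0, a0)] + [p for p in curve.points if p[0] > t0]
    t = np.array([p[0] for p in pts])
    a = np.array([p[1] for p in pts])
    if T_s < t[-1]:
        a_T = float(np.interp(T_s, t, a))
        keep = t < T_s
        t = np.append(t[keep], T_s)
        a = np.append(a[keep], a_T)
    return float(np.trapezoid(a, t))


def tail_integral(activity_at_T_Bq: float, nuclide: Nuclide) -> float:
    """Decays from T to infinity assuming physical decay only: A(T)/λ."""
    if activity_at_T_Bq < 0:
        raise ValidationError("activity must be ≥ 0")
    return activity_at_T_Bq / nuclide.decay_constant


def curve_from_measurements(
    measurements: Sequence[BiodistMeasurement],
    organ: str,
    nuclide: Nuclide,
    injected_Bq: float,
    organ_mass_g: float,
    boundary_rule: str = "plateau",
    apply_decay: bool = True,
) -> TimeActivityCurve:
    """Build an activity curve from group-mean %ID/g at each time point."""
    rows = [m for m in measurements if m.organ == organ]
    if not rows:
        raise MissingDataError(f"no measurements for organ {organ!r}")
    cells = summarize(rows)
    pts = sorted(
        (
            hours_to_seconds(c.time_h),
            activity_at(
                c.mean_pct_id_per_g, injected_Bq, organ_mass_g, nuclide,
                hours_to_seconds(c.time_h), apply_decay=apply_decay,
            ),
        )
        for c in cells
    )
    return TimeActivityCurve(organ, nuclide, tuple(pts), injected_Bq, boundary_rule)


def time_integrated_activity(
    measurements: Sequence[BiodistMeasurement],
    organ: str,
    nuclide: Nuclide,
    injected_Bq: float,
    organ_mass_g: float,
    T_s: float,
    boundary_rule: str = "plateau",
    apply_decay: bool = True,
) -> TimeIntegratedActivity:
    """AUC₀–T plus decay tail for one organ, from group-mean %ID/g."""
    curve = curve_from_measurements(
        measurements, organ, nuclide, injected_Bq, organ_mass_g,
        boundary_rule, apply_decay,
    )
    t_last, a_last = curve.points[-1]
    if t_last < T_s:
        warnings.warn(
            f"{organ}: last observation at {t_last / 3600:.1f} h precedes "
            f"T = {T_s / 3600:.1f} h; tail attached at the last observation",
            stacklevel=2,
        )
        T_eff = t_last
    else:
        T_eff = T_s
    auc = integrate_to_T(curve, T_eff)
    ts = np.array([p[0] for p in curve.points])
    activities = np.array([p[1] for p in curve.points])
    a_T = float(np.interp(T_eff, ts, activities))
    return TimeIntegratedActivity(organ, auc, tail_integral(a_T, nuclide), T_eff)


def tia_frame(tias: Sequence[TimeIntegratedActivity]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "organ": t.organ,
                "auc_0_T_Bq_s": t.auc_0_T_Bq_s,
                "tail_Bq_s": t.tail_Bq_s,
                "total_Bq_s": t.total_Bq_s,
                "T_s": t.T_s,
            }
            for t in tias
        ]
    )


def load_organ_masses(path: str | Path | None = None) -> dict[str, float]:
    """Organ-mass registry (g).  The bundled default is a literature-style
    30 g mouse; any two-column ``organ,mass_g`` table can replace it."""
    if path is None:
        source = resources.files("ricdosim").joinpath("data/organ_masses_mouse.csv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    if not {"organ", "mass_g"} <= set(df.columns):
        raise ValidationError("organ-mass table needs columns organ,mass_g")
    masses = {str(r.organ).strip().lower(): float(r.mass_g) for r in df.itertuples()}
    bad = [o for o, m in masses.items() if not (m > 0 and math.isfinite(m))]
    if bad:
        raise ValidationError(f"non-positive masses for: {bad}")
    return masses
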