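"""Organ dose computation from time-integrated activities and S-values.

The equivalent dose to a target region is

    D(target) = Σ_sources Ã(source) × S(target ← source) × W_R

with Ã in Bq·s, S in Gy per Bq·s and W_R the radiation weighting factor
(1 for β particles, γ rays and x-rays).  S-value tables are *inputs*: the
published phantom tables are third-party data, so this module reads any
delimited table of (source, target, S) pairs.  Self-dose-only tables
(cross-organ terms absent, treated as zero) are a first-class case.

Tumours are dosed by the unit-density sphere self-dose model: an S(mass)
curve interpolated log-log at the measured tumour mass.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MissingSValueError, RangeError, SchemaError, ValidationError
from .timeactivity import TimeIntegratedActivity
from .nuclides import Nuclide

REPORT_SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class SValueTable:
    nuclide: str
    phantom_id: str
    entries: Mapping[tuple[str, str], float]  # (source, target) -> Gy per Bq·s

    def __post_init__(self):
        for (src, tgt), s in self.entries.items():
            if s < 0 or not math.isfinite(s):
                raise ValidationError(f"S({tgt}←{src}) must be ≥ 0 and finite, got {s}")

    def sources(self) -> set[str]:
        return {src for src, _ in self.entries}

    def s(self, source: str, target: str) -> float:
        return self.entries.get((source, target), 0.0)


@dataclass(frozen=True)
class SphereSValueCurve:
    """Self-dose S vs mass for unit-density spheres, log-log interpolated."""

    nuclide: str
    nodes: tuple[tuple[float, float], ...]  # (mass_g, S) strictly increasing mass

    def __post_init__(self):
        if len(self.nodes) < 2:
            raise ValidationError("sphere curve needs ≥ 2 nodes")
        masses = [m for m, _ in self.nodes]
        svals = [s for _, s in self.nodes]
        if any(m2 <= m1 for m1, m2 in zip(masses, masses[1:])):
            raise ValidationError("sphere masses must be strictly increasing")
        if any(s2 >= s1 for s1, s2 in zip(svals, svals[1:])):
            raise ValidationError("sphere S must be strictly decreasing with mass")
        if any(not (m > 0 and s > 0) for m, s in self.nodes):
            raise ValidationError("sphere nodes must be positive")


@dataclass(frozen=True)
class DoseReport:
    """Per-target equivalent doses with the assumptions that produced them."""

    doses_Sv: Mapping[str, float]
    injected_MBq: float
    w_r: float
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if any(d < 0 for d in self.doses_Sv.values()):
            raise ValidationError("doses must be ≥ 0")
        if not (self.injected_MBq > 0):
            raise ValidationError("injected_MBq must be > 0")

    @property
    def doses_Sv_per_MBq(self) -> dict[str, float]:
        return {k: v / self.injected_MBq for k, v in self.doses_Sv.items()}

    @property
    def doses_mSv_per_MBq(self) -> dict[str, float]:
        return {k: 1000.0 * v / self.injected_MBq for k, v in self.doses_Sv.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "target": list(self.doses_Sv),
                "dose_Sv": list(self.doses_Sv.values()),
                "dose_Sv_per_MBq": [v / self.injected_MBq for v in self.doses_Sv.values()],
            }
        )

    def to_json_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "injected_MBq": self.injected_MBq,
            "w_r": self.w_r,
            "doses_Sv": dict(self.doses_Sv),
            "doses_Sv_per_MBq": self.doses_Sv_per_MBq,
            "provenance": dict(self.provenance),
        }

    def write(self, csv_path: str | Path | None = None, json_path: str | Path | None = None):
        if csv_path is not None:
            self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.to_json_dict(), indent=2))


def equivalent_dose(
    tias: Sequence[TimeIntegratedActivity],
    s_table: SValueTable,
    w_r: float = 1.0,
    injected_MBq: float = 1.0,
    provenance: Mapping[str, object] | None = None,
) -> DoseReport:
    """D(target) = Σ_sources Ã(source) · S(target←source) · W_R.

    Every Ã source must appear as a source in the table; targets are all
    targets the table defines for those sources.  Absent cross terms
    contribute zero, so a self-dose-only table gives D = Ã·S_self.
    """
    sources_have = s_table.sources()
    missing = [t.organ for t in tias if t.organ not in sources_have]
    if missing:
        raise MissingSValueError(missing)
    targets = sorted(
        {tgt for (src, tgt) in s_table.entries if any(t.organ == src for t in tias)}
    )
    doses: dict[str, float] = {}
    for tgt in targets:
        doses[tgt] = w_r * sum(t.total_Bq_s * s_table.s(t.organ, tgt) for t in tias)
    prov = dict(provenance or {})
    prov.setdefault("s_table", f"{s_table.nuclide}/{s_table.phantom_id}")
    prov.setdefault("w_r", w_r)
    return DoseReport(doses, injected_MBq, w_r, prov)


def sphere_s_value(mass_g: float, curve: SphereSValueCurve, clamp: bool = False) -> float:
    """Sphere self-dose S at the given mass, log-log interpolated.

    Exact at nodes; extrapolation is forbidden unless ``clamp`` is set,
    which returns the nearest node's S with a warning.
    """
    if not (mass_g > 0 and math.isfinite(mass_g)):
        raise ValidationError(f"mass must be > 0, got {mass_g}")
    masses = np.array([m for m, _ in curve.nodes])
    svals = np.array([s for _, s in curve.nodes])
    if mass_g < masses[0] or mass_g > masses[-1]:
        if not clamp:
            raise RangeError(
                f"mass {mass_g} g outside sphere curve range "
                f"[{masses[0]}, {masses[-1]}] g"
            )
        warnings.warn(
            f"mass {mass_g} g outside sphere curve range; clamping to nearest node",
            stacklevel=2,
        )
        return float(svals[0] if mass_g < masses[0] else svals[-1])
    return float(np.exp(np.interp(np.log(mass_g), np.log(masses), np.log(svals))))


def sphere_mass_from_diameter_cm(diameter_cm: float, density_g_per_cm3: float = 1.0) -> float:
    """Mass of a sphere of the given diameter (unit density by default)."""
    if not (diameter_cm > 0):
        raise ValidationError("diameter must be > 0")
    return density_g_per_cm3 * (4.0 / 3.0) * math.pi * (diameter_cm / 2.0) ** 3


def whole_body_tia(
    tias: Sequence[TimeIntegratedActivity],
    mode: str = "sum_of_sources",
) -> TimeIntegratedActivity:
    """Whole-body Ã, either a measured whole_body row or the organ sum."""
    if mode == "measured_row":
        for t in tias:
            if t.organ == "whole_body":
                return t
        raise ValidationError("measured_row requested but no whole_body TIA present")
    if mode != "sum_of_sources":
        raise ValidationError(f"unknown whole-body mode {mode!r}")
    organ_tias = [t for t in tias if t.organ != "whole_body"]
    T = max((t.T_s for t in organ_tias), default=0.0)
    return TimeIntegratedActivity(
        "whole_body",
        sum(t.auc_0_T_Bq_s for t in organ_tias),
        sum(t.tail_Bq_s for t in organ_tias),
        T,
    )


# ---------------------------------------------------------------- table I/O

def read_s_table(path: str | Path, sep: str = ",") -> SValueTable:
    """Read ``nuclide,phantom_id,source,target,S_Gy_per_Bq_s`` text."""
    df = pd.read_csv(path, sep=sep)
    required = {"nuclide", "phantom_id", "source", "target", "S_Gy_per_Bq_s"}
    if not required <= set(df.columns):
        raise SchemaError(f"{path}: S-value table needs columns {sorted(required)}")
    nuclides = df["nuclide"].unique()
    phantoms = df["phantom_id"].unique()
    if len(nuclides) != 1 or len(phantoms) != 1:
        raise SchemaError(f"{path}: one nuclide and one phantom per table")
    entries = {
        (str(r.source).lower(), str(r.target).lower()): float(r.S_Gy_per_Bq_s)
        for r in df.itertuples()
    }
    return SValueTable(str(nuclides[0]), str(phantoms[0]), entries)


def write_s_table(table: SValueTable, path: str | Path, sep: str = ",") -> None:
    rows = [
        {
            "nuclide": table.nuclide,
            "phantom_id": table.phantom_id,
            "source": src,
            "target": tgt,
            "S_Gy_per_Bq_s": s,
        }
        for (src, tgt), s in table.entries.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_sphere_curve(path: str | Path, sep: str = ",") -> SphereSValueCurve:
    """Read ``nuclide,mass_g,S_Gy_per_Bq_s`` text, sorted by mass."""
    df = pd.read_csv(path, sep=sep)
    required = {"nuclide", "mass_g", "S_Gy_per_Bq_s"}
    if not required <= set(df.columns):
        raise SchemaError(f"{path}: sphere curve needs columns {sorted(required)}")
    nuclides = df["nuclide"].unique()
    if len(nuclides) != 1:
        raise SchemaError(f"{path}: one nuclide per sphere curve")
    df = df.sort_values("mass_g")
    nodes = tuple((float(r.mass_g), float(r.S_Gy_per_Bq_s)) for r in df.itertuples())
    return SphereSValueCurve(str(nuclides[0]), nodes)


def write_sphere_curve(curve: SphereSValueCurve, path: str | Path, sep: str = ",") -> None:
    pd.DataFrame(
        [
            {"nuclide": curve.nuclide, "mass_g": m, "S_Gy_per_Bq_s": s}
            for m, s in curve.nodes
        ]
    ).to_csv(path, sep=sep, index=False)


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
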