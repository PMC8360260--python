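"""Per-animal biodistribution tables (%ID/g) and group summaries.

The raw input of the whole pipeline is a tidy, long-format table with one
row per animal × organ × time point:

    subject_id,group_id,organ,time_h,pct_id_per_g[,organ_mass_g,
        injected_activity_MBq,injected_protein_ug]

%ID/g values are taken as decay-corrected at measurement; physical decay
is re-applied downstream in the activity formula (a flag there can skip
it for tables that are not decay-corrected).

Summaries report mean ± SEM per (group, organ, time) cell, matching the
wide biodistribution tables conventionally published for groups of 3–5
mice sacrificed per time point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

# Controlled organ vocabulary; extensible via extra_organs= in read_biodist.
ORGANS = frozenset(
    {
        "heart", "lungs", "stomach", "pancreas", "intestine", "spleen",
        "liver", "kidneys", "bone", "skin", "muscle", "blood", "tumour",
        "whole_body",
    }
)

# Case-insensitive synonym map (both spellings occur in published tables).
ORGAN_SYNONYMS = {
    "intestines": "intestine",
    "tumor": "tumour",
    "kidney": "kidneys",
    "lung": "lungs",
    "whole body": "whole_body",
    "wholebody": "whole_body",
}

_REQUIRED_COLUMNS = ["subject_id", "group_id", "organ", "time_h", "pct_id_per_g"]
_OPTIONAL_COLUMNS = ["organ_mass_g", "injected_activity_MBq", "injected_protein_ug"]


def canonical_organ(name: str, extra_organs: frozenset[str] | set[str] = frozenset()) -> str:
    key = str(name).strip().lower()
    key = ORGAN_SYNONYMS.get(key, key)
    if key not in ORGANS and key not in extra_organs:
        raise ValidationError(f"unknown organ {name!r}")
    return key


@dataclass(frozen=True)
class BiodistMeasurement:
    """One animal's %ID/g in one organ at one time post-injection."""

    subject_id: str
    group_id: str
    organ: str
    time_h: float
    pct_id_per_g: float
    organ_mass_g: float | None = None
    injected_activity_MBq: float | None = None
    injected_protein_ug: float | None = None

    def __post_init__(self):
        if self.pct_id_per_g < 0 or not math.isfinite(self.pct_id_per_g):
            raise ValidationError(f"pct_id_per_g must be ≥ 0, got {self.pct_id_per_g}")
        if self.time_h < 0 or not math.isfinite(self.time_h):
            raise ValidationError(f"time_h must be ≥ 0, got {self.time_h}")
        for attr in ("organ_mass_g", "injected_activity_MBq", "injected_protein_ug"):
            v = getattr(self, attr)
            if v is not None and not (v > 0 and math.isfinite(v)):
                raise ValidationError(f"{attr} must be > 0 when present, got {v}")


@dataclass(frozen=True)
class BiodistSummary:
    """Group mean ± SEM for one (group, organ, time) cell."""

    group_id: str
    organ: str
    time_h: float
    mean_pct_id_per_g: float
    sem: float
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("n must be ≥ 1")
        if self.sem < 0:
            raise ValidationError("sem must be ≥ 0")
        if self.n == 1 and self.sem != 0:
            raise ValidationError("sem must be 0 when n = 1")


def read_biodist(
    path: str | Path,
    sep: str | None = None,
    extra_organs: Iterable[str] = (),
) -> list[BiodistMeasurement]:
    """Read and validate a tidy biodistribution table.

    Comma-delimited by default; tab accepted (``sep`` is sniffed when not
    given).  Every row is validated; schema errors name the offending
    1-based data row.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    if sep is None:
        header = path.open("r", encoding="utf-8").readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    extra = frozenset(str(o).strip().lower() for o in extra_organs)

    out: list[BiodistMeasurement] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        try:
            organ = canonical_organ(d["organ"], extra)
            kwargs = {}
            for c in _OPTIONAL_COLUMNS:
                v = d.get(c)
                if v is not None and not (isinstance(v, float) and math.isnan(v)):
                    kwargs[c] = float(v)
            out.append(
                BiodistMeasurement(
                    subject_id=str(d["subject_id"]),
                    group_id=str(d["group_id"]),
                    organ=organ,
                    time_h=float(d["time_h"]),
                    pct_id_per_g=float(d["pct_id_per_g"]),
                    **kwargs,
                )
            )
        except (ValidationError, ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: row {i}: {exc}") from exc
    return out


def write_biodist(measurements: Sequence[BiodistMeasurement], path: str | Path, sep: str = ",") -> None:
    df = to_frame(measurements)
    df.to_csv(path, sep=sep, index=False)


def to_frame(measurements: Sequence[BiodistMeasurement]) -> pd.DataFrame:
    cols = _REQUIRED_COLUMNS + _OPTIONAL_COLUMNS
    if not measurements:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([asdict(m) for m in measurements], columns=cols)


def summarize(measurements: Sequence[BiodistMeasurement]) -> list[BiodistSummary]:
    """Mean and SEM (sample SD / √n) per (group, organ, time) cell.

    Empty input yields an empty list.  Order follows first appearance of
    each cell; the statistics themselves are permutation-invariant.
    """
    if not measurements:
        return []
    df = to_frame(measurements)
    out: list[BiodistSummary] = []
    for (group, organ, time_h), grp in df.groupby(
        ["group_id", "organ", "time_h"], sort=False
    ):
        vals = grp["pct_id_per_g"].to_numpy(dtype=float)
        n = len(vals)
        sem = 0.0 if n == 1 else float(np.std(vals, ddof=1) / math.sqrt(n))
        out.append(
            BiodistSummary(
                group_id=str(group),
                organ=str(organ),
                time_h=float(time_h),
                mean_pct_id_per_g=float(np.mean(vals)),
                sem=sem,
                n=n,
            )
        )
    return out


def summary_frame(summaries: Sequence[BiodistSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_id": s.group_id,
                "organ": s.organ,
                "time_h": s.time_h,
                "mean": s.mean_pct_id_per_g,
                "sem": s.sem,
                "n": s.n,
            }
            for s in summaries
        ],
        columns=["group_id", "organ", "time_h", "mean", "sem", "n"],
    )


def write_summary(summaries: Sequence[BiodistSummary], path: str | Path, sep: str = ",") -> None:
    summary_frame(summaries).to_csv(path, sep=sep, index=False)


def chelator_substitution(bound_fraction: float, molar_excess: float) -> float:
    """Chelators conjugated per protein from a trace-labeling assay.

    The fraction of label bound to protein, multiplied by the molar excess
    of activated chelator used in the conjugation reaction (e.g. a 0.19
    bound fraction at a 20:1 ratio gives 3.8 chelators per protein).
    """
    if not (0.0 <= bound_fraction <= 1.0):
        raise ValidationError(f"bound_fraction must be in [0, 1], got {bound_fraction}")
    if not (molar_excess > 0 and math.isfinite(molar_excess)):
        raise ValidationError(f"molar_excess must be > 0, got {molar_excess}")
    return bound_fraction * molar_excess
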