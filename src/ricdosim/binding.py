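"""Saturation radioligand binding: NSB subtraction and one-site Kd/Bmax fit.

Total binding (TB) is measured over an increasing free-ligand
concentration series; non-specific binding (NSB) is the parallel arm with
excess unlabeled competitor and is modeled as linear in free
concentration.  Specific binding SB = TB − NSB (floored at zero) is fit
to the one-site hyperbola

    SB(F) = Bmax · F / (Kd + F)

by constrained least squares.  Bmax converts to receptors per cell via
Avogadro's number.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitFailureError, SchemaError, ValidationError

AVOGADRO = 6.02214e23


@dataclass(frozen=True)
class BindingObservation:
    """One tube of a saturation assay (both arms at one concentration)."""

    free_conc_nM: float
    total_bound_pmol: float
    nonspecific_bound_pmol: float
    n_cells: float = 1e6
    volume_L: float = 200e-6

    def __post_init__(self):
        for attr in ("free_conc_nM", "total_bound_pmol", "nonspecific_bound_pmol"):
            v = getattr(self, attr)
            if v < 0 or not math.isfinite(v):
                raise ValidationError(f"{attr} must be ≥ 0, got {v}")
        if not (self.n_cells > 0 and self.volume_L > 0):
            raise ValidationError("n_cells and volume_L must be > 0")


@dataclass(frozen=True)
class OneSiteFit:
    kd_nM: float
    bmax_pmol: float
    ns_slope: float  # pmol per nM, NSB line
    kd_se: float
    bmax_se: float
    receptors_per_cell: float
    n_points: int
    residual_ss: float
    converged: bool

    def to_json_dict(self) -> dict:
        return {
            "kd_nM": self.kd_nM,
            "bmax_pmol": self.bmax_pmol,
            "ns_slope_pmol_per_nM": self.ns_slope,
            "kd_se": self.kd_se,
            "bmax_se": self.bmax_se,
            "receptors_per_cell": self.receptors_per_cell,
            "n_points": self.n_points,
            "residual_ss": self.residual_ss,
            "converged": self.converged,
        }


def specific_binding(tb: float, nsb: float) -> float:
    """SB = TB − NSB, floored at zero (with a warning when TB < NSB)."""
    if tb < 0 or nsb < 0:
        raise ValidationError("TB and NSB must be ≥ 0")
    if tb < nsb:
        warnings.warn(
            f"total bound ({tb}) below non-specific bound ({nsb}); "
            "specific binding floored at 0",
            stacklevel=2,
        )
        return 0.0
    return tb - nsb


def receptors_per_cell(bmax_pmol: float, n_cells: float) -> float:
    """Binding sites per cell: Bmax (pmol) × 10⁻¹² × N_A / n_cells."""
    if bmax_pmol < 0:
        raise ValidationError("bmax_pmol must be ≥ 0")
    if not (n_cells > 0):
        raise ValidationError("n_cells must be > 0")
    return bmax_pmol * 1e-12 * AVOGADRO / n_cells


def _one_site(F, bmax, kd):
    return bmax * F / (kd + F)


def fit_one_site(
    observations: Sequence[BindingObservation],
    mode: str = "subtract",
    weighting: str = "none",
    depletion_corrected: bool = False,
) -> OneSiteFit:
    """Fit Kd and Bmax from a saturation assay.

    ``subtract`` mode (default, the classical procedure) fits the
    hyperbola to SB = TB − NSB, with the NSB slope estimated separately
    from the NSB arm by closed-form least squares through the origin.
    ``joint`` mode fits TB = Bmax·F/(Kd+F) + ns·F in one regression.
    ``weighting='1/y2'`` applies relative (1/Y²) weights.  The nominal
    free concentration is used unless ``depletion_corrected``, which
    subtracts bound ligand from the added concentration.
    """
    if len(observations) < 4:
        raise ValidationError("need ≥ 4 observations to fit a one-site model")
    if mode not in ("subtract", "joint"):
        raise ValidationError(f"unknown fit mode {mode!r}")
    if weighting not in ("none", "1/y2"):
        raise ValidationError(f"unknown weighting {weighting!r}")

    F = np.array([o.free_conc_nM for o in observations], dtype=float)
    tb = np.array([o.total_bound_pmol for o in observations], dtype=float)
    nsb = np.array([o.nonspecific_bound_pmol for o in observations], dtype=float)
    vol = np.array([o.volume_L for o in observations], dtype=float)
    if len(np.unique(F)) < 4:
        raise ValidationError("need ≥ 4 distinct free concentrations")
    if depletion_corrected:
        # pmol bound / (L × 1e-3) = nM depletion
        F = np.maximum(F - tb * 1e-3 / vol, 1e-12)

    ns_slope = float(np.sum(F * nsb) / np.sum(F * F))

    if mode == "subtract":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sb = np.array([specific_binding(t, n) for t, n in zip(tb, nsb)])
        y = sb
        model = _one_site
        p0 = [max(y.max(), 1e-6), _half_max_conc(F, y)]
        bounds = ([0.0, 1e-12], [np.inf, np.inf])
    else:
        y = tb

        def model(Fv, bmax, kd, ns):
            return _one_site(Fv, bmax, kd) + ns * Fv

        p0 = [max(tb.max() - ns_slope * F.max(), 1e-6), _half_max_conc(F, tb), ns_slope]
        bounds = ([0.0, 1e-12, 0.0], [np.inf, np.inf, np.inf])

    sigma = None
    if weighting == "1/y2":
        sigma = np.maximum(np.abs(y), 1e-6 * max(y.max(), 1e-12))

    try:
        popt, pcov = curve_fit(
            model, F, y, p0=p0, sigma=sigma, absolute_sigma=False,
            bounds=bounds, maxfev=20_000,
        )
    except RuntimeError as exc:
        raise FitFailureError(f"one-site fit did not converge: {exc}") from exc

    bmax, kd = float(popt[0]), float(popt[1])
    if mode == "joint":
        ns_slope = float(popt[2])
    perr = np.sqrt(np.diag(pcov))
    bmax_se, kd_se = float(perr[0]), float(perr[1])

    f_min, f_max = float(F.min()), float(F.max())
    # a Kd far outside the designed concentration range is not identified
    # by the assay, whatever the optimizer reports
    if kd < 0.01 * f_min or kd > 100 * f_max or not math.isfinite(kd_se):
        raise FitFailureError(
            "fitted Kd pinned at a bound or outside the designed range",
            diagnostics={"kd_nM": kd, "bmax_pmol": bmax,
                         "f_min_nM": f_min, "f_max_nM": f_max},
        )

    resid = y - model(F, *popt)
    n_cells = float(np.median([o.n_cells for o in observations]))
    return OneSiteFit(
        kd_nM=kd,
        bmax_pmol=bmax,
        ns_slope=ns_slope,
        kd_se=kd_se,
        bmax_se=bmax_se,
        receptors_per_cell=receptors_per_cell(bmax, n_cells),
        n_points=len(observations),
        residual_ss=float(np.sum(resid**2)),
        converged=True,
    )


def _half_max_conc(F: np.ndarray, y: np.ndarray) -> float:
    # concentration nearest half-maximal response, as a Kd starting value
    if y.max() <= 0:
        return float(np.median(F))
    idx = int(np.argmin(np.abs(y - y.max() / 2.0)))
    return max(float(F[idx]), 1e-6)


def read_binding_assay(path: str | Path, sep: str = ",") -> list[BindingObservation]:
    """Read ``free_conc_nM,total_bound_pmol,nonspecific_bound_pmol
    [,n_cells,volume_L]`` text."""
    df = pd.read_csv(path, sep=sep)
    required = {"free_conc_nM", "total_bound_pmol", "nonspecific_bound_pmol"}
    if not required <= set(df.columns):
        raise SchemaError(f"{path}: binding table needs columns {sorted(required)}")
    out = []
    for i, r in enumerate(df.itertuples(index=False), start=1):
        d = r._asdict()
        try:
            kwargs = {}
            for c in ("n_cells", "volume_L"):
                if c in d and d[c] is not None and not (
                    isinstance(d[c], float) and math.isnan(d[c])
                ):
                    kwargs[c] = float(d[c])
            out.append(
                BindingObservation(
                    float(d["free_conc_nM"]),
                    float(d["total_bound_pmol"]),
                    float(d["nonspecific_bound_pmol"]),
                    **kwargs,
                )
            )
        except (ValidationError, ValueError) as exc:
            raise SchemaError(f"{path}: row {i}: {exc}") from exc
    return out


def write_binding_assay(
    observations: Sequence[BindingObservation], path: str | Path, sep: str = ","
) -> None:
    pd.DataFrame(
        [
            {
                "free_conc_nM": o.free_conc_nM,
                "total_bound_pmol": o.total_bound_pmol,
                "nonspecific_bound_pmol": o.nonspecific_bound_pmol,
                "n_cells": o.n_cells,
                "volume_L": o.volume_L,
            }
            for o in observations
        ]
    ).to_csv(path, sep=sep, index=False)


def write_fit_report(fit: OneSiteFit, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit.to_json_dict(), indent=2))
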