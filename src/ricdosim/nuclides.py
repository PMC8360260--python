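"""Radionuclide decay math and the nuclide registry.

Every downstream stage (time–activity integration, dose computation,
human projection) depends on a physical decay constant λ = ln 2 / t½.
The registry ships Cu-64 (t½ = 12.7 h) and Lu-177 (t½ = 6.7 d) read from
a bundled delimited-text table; user tables with the same schema can be
loaded with :func:`load_registry`.

Emission metadata (kind, energy, abundance) is carried for provenance
only — dose computation goes through S-values, which already encapsulate
the emission spectrum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import MissingDataError, ValidationError

LN2 = math.log(2.0)

EMISSION_KINDS = frozenset({"beta-", "beta+", "gamma", "x-ray"})


@dataclass(frozen=True)
class Emission:
    kind: str
    energy_MeV: float
    abundance_fraction: float

    def __post_init__(self):
        if self.kind not in EMISSION_KINDS:
            raise ValidationError(f"unknown emission kind {self.kind!r}")
        if not (self.energy_MeV > 0 and math.isfinite(self.energy_MeV)):
            raise ValidationError("emission energy must be positive and finite")
        if not (0.0 <= self.abundance_fraction <= 1.0):
            raise ValidationError("abundance_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class Nuclide:
    """A radionuclide with its physical half-life in seconds.

    ``decay_constant`` is derived, never stored independently, so the
    invariant λ·t½ = ln 2 holds by construction.
    """

    name: str
    half_life_s: float
    emissions: tuple[Emission, ...] = field(default=())

    def __post_init__(self):
        if not (self.half_life_s > 0 and math.isfinite(self.half_life_s)):
            raise ValidationError("half_life_s must be positive and finite")

    @property
    def decay_constant(self) -> float:
        """Decay rate λ in s⁻¹ (often written k in dosimetry formulas)."""
        return decay_constant(self.half_life_s)


def decay_constant(half_life_s: float) -> float:
    """Return λ = ln 2 / t½ in s⁻¹ for a half-life in seconds."""
    if not (half_life_s > 0 and math.isfinite(half_life_s)):
        raise ValidationError(f"half-life must be positive and finite, got {half_life_s!r}")
    return LN2 / half_life_s


def decay_factor(nuclide: Nuclide, t_s: float) -> float:
    """Fraction of activity remaining after ``t_s`` seconds: exp(−λt)."""
    if t_s < 0 or not math.isfinite(t_s):
        raise ValidationError(f"time must be non-negative and finite, got {t_s!r}")
    return math.exp(-nuclide.decay_constant * t_s)


def hours_to_seconds(t_h: float) -> float:
    return t_h * 3600.0


def _normalise_name(name: str) -> str:
    # "cu64", "64Cu", "Cu-64" all resolve to "cu-64"
    s = name.strip().lower().replace("_", "-")
    if "-" not in s:
        digits = "".join(c for c in s if c.isdigit())
        letters = "".join(c for c in s if c.isalpha())
        if digits and letters:
            s = f"{letters}-{digits}"
    return s


def load_registry(path: str | Path | None = None) -> dict[str, Nuclide]:
    """Load a nuclide table (bundled by default) into a name → Nuclide map.

    Schema: ``name,half_life_s,emission_kind,energy_MeV,abundance_fraction``
    with one row per emission line; ``half_life_s`` must agree across rows
    of the same nuclide.
    """
    if path is None:
        source = resources.files("ricdosim").joinpath("data/nuclides.csv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"name", "half_life_s", "emission_kind", "energy_MeV", "abundance_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"nuclide table missing columns: {sorted(missing)}")
    registry: dict[str, Nuclide] = {}
    for name, grp in df.groupby("name", sort=False):
        half_lives = grp["half_life_s"].unique()
        if len(half_lives) != 1:
            raise ValidationError(f"inconsistent half-lives for {name}: {half_lives}")
        emissions = tuple(
            Emission(r.emission_kind, float(r.energy_MeV), float(r.abundance_fraction))
            for r in grp.itertuples()
        )
        registry[_normalise_name(str(name))] = Nuclide(str(name), float(half_lives[0]), emissions)
    return registry


_DEFAULT_REGISTRY: dict[str, Nuclide] | None = None


def get_nuclide(name: str, registry: dict[str, Nuclide] | None = None) -> Nuclide:
    """Look up a nuclide by name (case/format-insensitive: '64Cu', 'Cu-64', ...)."""
    global _DEFAULT_REGISTRY
    if registry is None:
        if _DEFAULT_REGISTRY is None:
            _DEFAULT_REGISTRY = load_registry()
        registry = _DEFAULT_REGISTRY
    key = _normalise_name(name)
    if key not in registry:
        raise MissingDataError(
            f"nuclide {name!r} not in registry (have: {sorted(registry)})"
        )
    return registry[key]


def mean_beta_like_energy_MeV(emissions: Sequence[Emission]) -> float:
    """Abundance-weighted mean emission energy per decay (metadata helper)."""
    return sum(e.energy_MeV * e.abundance_fraction for e in emissions)
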