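"""Phantom geometry surrogate: region masses, blood content, SAF tables.

The phantom description is a JSON file holding the region catalogue of a
sex-specific reference phantom (names, masses, wall/content links,
fractional blood content) plus a substitution map for source regions the
SAF compilation does not cover (e.g. heart contents substituting for the
aorta).

Specific absorbed fractions Φ(target ← source, E) arrive as a long-format
CSV over an energy grid per (target, source, radiation type).  Lookup
between grid points is log–log linear — the field convention for the
smooth power-law-like energy dependence of SAFs — with a linear fallback
on intervals where an endpoint is zero.  Below the lowest simulated
energy the value at that cutoff energy is used (a deliberately
restrictive policy); above the grid the highest-energy value is used.
Both out-of-grid policies can be overridden.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import TOTAL_BODY, normalize_region
from .errors import FormatError, MissingGeometryError
from .nucleardata import RADIATION_TYPES

SAF_COLUMNS = ("target", "source", "radiation_type", "energy_MeV", "saf_per_kg")


@dataclass(frozen=True)
class Region:
    """A phantom region: identity, role, mass and optional blood share."""

    name: str
    kind: str  # source | target | both
    mass_kg: float
    wall_of: str | None = None
    blood_fraction: float | None = None

    def __post_init__(self):
        if self.kind not in ("source", "target", "both"):
            raise ValueError(f"region {self.name!r}: bad kind {self.kind!r}")
        if not self.mass_kg > 0:
            raise ValueError(f"region {self.name!r}: mass must be > 0, got {self.mass_kg}")
        if self.blood_fraction is not None and not 0.0 <= self.blood_fraction <= 1.0:
            raise ValueError(
                f"region {self.name!r}: blood fraction {self.blood_fraction} not in [0, 1]"
            )


@dataclass
class Phantom:
    """Sex-specific reference phantom surrogate."""

    sex: str
    regions: tuple[Region, ...]
    total_body_mass_kg: float
    substitutions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not self.total_body_mass_kg > 0:
            raise ValueError("total body mass must be > 0")
        self.regions = tuple(self.regions)
        self._by_name = {r.name: r for r in self.regions}
        blood_total = sum(r.blood_fraction or 0.0 for r in self.regions)
        if blood_total > 1.0 + 1e-9:
            raise ValueError(f"blood fractions sum to {blood_total} > 1")
        for src, sub in self.substitutions.items():
            if sub not in self._by_name:
                raise ValueError(f"substitution target {sub!r} (for {src!r}) not a phantom region")

    def region(self, name: str) -> Region:
        key = normalize_region(name)
        try:
            return self._by_name[key]
        except KeyError:
            raise KeyError(f"region {name!r} not present in {self.sex} phantom") from None

    def mass(self, name: str) -> float:
        """Mass of a region in kg; ``total body`` resolves to the body mass."""
        key = normalize_region(name)
        if key == TOTAL_BODY:
            return self.total_body_mass_kg
        return self.region(key).mass_kg

    def has_region(self, name: str) -> bool:
        return normalize_region(name, strict=False) in self._by_name

    def blood_fractions(self) -> dict[str, float]:
        return {
            r.name: r.blood_fraction for r in self.regions if r.blood_fraction is not None
        }

    def resolve_source(self, name: str) -> tuple[str, bool]:
        """Apply the substitution map; returns (resolved name, substituted?)."""
        key = normalize_region(name)
        if key in self.substitutions:
            return self.substitutions[key], True
        return key, False


def load_phantom(path: str | Path) -> Phantom:
    """Load and validate a phantom-JSON file.

    Region names are normalized against the canonical catalogue
    (case/space-insensitive, aliases resolved); unknown names raise with
    the nearest catalogue candidates.
    """
    path = Path(path)
    data = json.loads(path.read_text(encoding="utf-8"))
    try:
        sex = data["sex"]
        total = float(data["total_body_mass_kg"])
        raw_regions = data["regions"]
    except KeyError as exc:
        raise FormatError(f"{path}: missing phantom field {exc}") from None
    regions = []
    for rec in raw_regions:
        try:
            name = normalize_region(rec["name"])
            wall_of = rec.get("wall_of")
            region = Region(
                name=name,
                kind=rec.get("kind", "both"),
                mass_kg=float(rec["mass_kg"]),
                wall_of=normalize_region(wall_of) if wall_of else None,
                blood_fraction=(
                    float(rec["blood_fraction"]) if rec.get("blood_fraction") is not None else None
                ),
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise FormatError(f"{path}: bad region record {rec!r}: {exc}") from None
        regions.append(region)
    substitutions = {
        normalize_region(k): normalize_region(v)
        for k, v in (data.get("substitutions") or {}).items()
    }
    return Phantom(sex=sex, regions=tuple(regions), total_body_mass_kg=total,
                   substitutions=substitutions)


@dataclass(frozen=True)
class SAFPolicy:
    """Out-of-grid lookup policy (both sides default to clamping)."""

    below_grid: str = "clamp"  # clamp (cutoff value) | error
    above_grid: str = "clamp"  # clamp | error


class SAFTable:
    """Energy-gridded specific absorbed fractions per (target ← source, type)."""

    def __init__(self, entries: dict[tuple[str, str, str], tuple[np.ndarray, np.ndarray]]):
        self.entries = {}
        cutoffs: dict[str, float] = {}
        for (target, source, rtype), (energies, values) in entries.items():
            energies = np.asarray(energies, dtype=float)
            values = np.asarray(values, dtype=float)
            if energies.size < 2:
                raise ValueError(
                    f"SAF grid for ({target}, {source}, {rtype}) needs >= 2 points"
                )
            if not np.all(np.diff(energies) > 0):
                raise ValueError(
                    f"SAF energy grid for ({target}, {source}, {rtype}) not strictly increasing"
                )
            if np.any(values < 0):
                raise ValueError(f"negative SAF for ({target}, {source}, {rtype})")
            self.entries[(target, source, rtype)] = (energies, values)
            low = float(energies[0])
            cutoffs[rtype] = min(cutoffs.get(rtype, low), low)
        #: lowest simulated energy per radiation type
        self.cutoff_energy_mev = cutoffs

    def __contains__(self, key):
        return key in self.entries

    def targets(self) -> list[str]:
        return sorted({t for t, _, _ in self.entries})

    def sources(self) -> list[str]:
        return sorted({s for _, s, _ in self.entries})

    def radiation_types(self) -> list[str]:
        return sorted({r for _, _, r in self.entries})


def load_saf(path: str | Path) -> SAFTable:
    """Load a long-format SAF-CSV file into an :class:`SAFTable`."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in SAF_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    bad_types = set(df["radiation_type"]) - RADIATION_TYPES
    if bad_types:
        raise FormatError(f"{path}: unknown radiation types {sorted(bad_types)}")
    df = df.assign(
        target=[normalize_region(t) for t in df["target"]],
        source=[normalize_region(s) for s in df["source"]],
    )
    dup = df.duplicated(subset=["target", "source", "radiation_type", "energy_MeV"])
    if dup.any():
        first = df[dup].iloc[0]
        raise FormatError(
            f"{path}: duplicate SAF row for ({first['target']}, {first['source']}, "
            f"{first['radiation_type']}, E={first['energy_MeV']})"
        )
    entries = {}
    for (target, source, rtype), grp in df.groupby(
        ["target", "source", "radiation_type"], sort=False
    ):
        grp = grp.sort_values("energy_MeV")
        try:
            entries[(target, source, rtype)] = (
                grp["energy_MeV"].to_numpy(dtype=float),
                grp["saf_per_kg"].to_numpy(dtype=float),
            )
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric SAF data for ({target}, {source}, {rtype}): {exc}")
    try:
        return SAFTable(entries)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def saf_lookup(
    table: SAFTable,
    target: str,
    source: str,
    rtype: str,
    energy_mev: float,
    policy: SAFPolicy = SAFPolicy(),
) -> float:
    """Specific absorbed fraction Φ(target ← source, E) in kg⁻¹.

    Grid energies return the tabulated value exactly; between grid
    points the value is log–log interpolated (linear where an endpoint
    is zero); outside the grid the policy applies (default: clamp to the
    cutoff / highest-energy value).
    """
    if not energy_mev > 0:
        raise ValueError(f"energy must be > 0, got {energy_mev}")
    key = (normalize_region(target), normalize_region(source), rtype)
    try:
        energies, values = table.entries[key]
    except KeyError:
        raise MissingGeometryError(*key) from None
    if energy_mev <= energies[0]:
        if energy_mev < energies[0] and policy.below_grid == "error":
            raise ValueError(f"energy {energy_mev} MeV below SAF grid for {key}")
        return float(values[0])
    if energy_mev >= energies[-1]:
        if energy_mev > energies[-1] and policy.above_grid == "error":
            raise ValueError(f"energy {energy_mev} MeV above SAF grid for {key}")
        return float(values[-1])
    i = int(np.searchsorted(energies, energy_mev))
    if energies[i] == energy_mev:
        return float(values[i])
    e0, e1 = energies[i - 1], energies[i]
    v0, v1 = values[i - 1], values[i]
    if v0 > 0.0 and v1 > 0.0:
        t = (math.log(energy_mev) - math.log(e0)) / (math.log(e1) - math.log(e0))
        return float(math.exp(math.log(v0) + t * (math.log(v1) - math.log(v0))))
    t = (energy_mev - e0) / (e1 - e0)
    return float(v0 + t * (v1 - v0))
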