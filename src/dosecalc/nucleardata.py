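"""Nuclide decay data: emission spectra (type, energy, yield) per transformation.

The decay-CSV dialect emulates a decay-data compilation: a header line
``# energy_unit=<MeV|keV>`` followed by columns
``nuclide,half_life_h,radiation_type,energy,yield``.  Energies are held
internally in MeV.  Beta transitions may be given either as a single
mean-energy line carrying the full transition yield, or as spectrum
bins (one row per bin with per-bin intensities, flagged via an optional
``spectrum_bin`` column); both feed the Δ = E·Y formalism identically.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .errors import FormatError

RADIATION_TYPES = frozenset({"photon", "electron", "beta_minus", "beta_plus", "alpha"})

#: Radiation weighting factors.  Every radiation type used in diagnostic
#: nuclear medicine carries w_R = 1; alpha particles (never used
#: diagnostically, but parseable) carry the protection-quantity value 20.
DEFAULT_WR = {"alpha": 20.0}

_COLUMNS = ("nuclide", "half_life_h", "radiation_type", "energy", "yield")


@dataclass(frozen=True)
class RadiationEmission:
    """One emission line: type, energy (MeV), yield per transformation."""

    radiation_type: str
    energy_mev: float
    yield_per_decay: float
    w_r: float = field(default=None)  # type: ignore[assignment]
    spectrum_bin: bool = False

    def __post_init__(self):
        if self.radiation_type not in RADIATION_TYPES:
            raise ValueError(
                f"unknown radiation type {self.radiation_type!r}; "
                f"expected one of {sorted(RADIATION_TYPES)}"
            )
        if not self.energy_mev > 0:
            raise ValueError(f"emission energy must be > 0, got {self.energy_mev}")
        if self.yield_per_decay < 0:
            raise ValueError(f"emission yield must be >= 0, got {self.yield_per_decay}")
        if self.w_r is None:
            object.__setattr__(self, "w_r", DEFAULT_WR.get(self.radiation_type, 1.0))

    @property
    def delta_mev(self) -> float:
        """Mean energy emitted per transformation, Δ = E·Y (MeV)."""
        return self.energy_mev * self.yield_per_decay


@dataclass(frozen=True)
class Nuclide:
    """A radionuclide: physical half-life (hours) and its emission list.

    Progeny are not followed; every computation concerns one nuclide.
    """

    name: str
    half_life_h: float
    emissions: tuple[RadiationEmission, ...]

    def __post_init__(self):
        if not self.half_life_h > 0:
            raise ValueError(f"physical half-life must be > 0, got {self.half_life_h}")
        object.__setattr__(self, "emissions", tuple(self.emissions))
        if not self.emissions:
            raise ValueError(f"nuclide {self.name!r} has an empty emission list")
        total = sum(e.delta_mev for e in self.emissions)
        if not math.isfinite(total) or total < 0:
            raise ValueError(
                f"nuclide {self.name!r}: total emitted energy per decay "
                f"must be finite and non-negative, got {total}"
            )

    @property
    def decay_constant_per_h(self) -> float:
        """Physical decay constant λ = ln2 / T½ (h⁻¹)."""
        return math.log(2.0) / self.half_life_h


def total_energy_per_decay(nuclide: Nuclide) -> float:
    """Total mean energy emitted per nuclear transformation, Σᵢ EᵢYᵢ (MeV)."""
    return sum(e.delta_mev for e in nuclide.emissions)


def parse_decay_file(path: str | Path) -> list[Nuclide]:
    """Parse a decay-CSV file into a list of :class:`Nuclide`.

    One nuclide per distinct name, emissions preserved in file order;
    energies declared in keV are converted to MeV.  Duplicate identical
    emission rows are kept with a warning (some compilations list
    coincident lines separately).
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].lstrip().startswith("#"):
        raise FormatError(f"{path}: missing '# energy_unit=<MeV|keV>' header line")
    header = lines[0].lstrip("# ").strip()
    try:
        key, unit = (s.strip() for s in header.split("="))
    except ValueError:
        raise FormatError(f"{path}: malformed header {header!r}") from None
    if key != "energy_unit" or unit not in ("MeV", "keV"):
        raise FormatError(f"{path}: malformed energy-unit header {header!r}")
    scale = 1.0 if unit == "MeV" else 1e-3

    reader = csv.DictReader(lines[1:])
    if reader.fieldnames is None:
        raise FormatError(f"{path}: empty file")
    fields = [f.strip() for f in reader.fieldnames]
    for col in _COLUMNS:
        if col not in fields:
            raise FormatError(f"{path}: missing required column {col!r}")

    per_nuclide: dict[str, dict] = {}
    seen_rows: set[tuple] = set()
    for lineno, row in enumerate(reader, start=3):  # header line + column line
        name = (row.get("nuclide") or "").strip()
        if not name:
            raise FormatError(f"{path}:{lineno}: empty nuclide name")
        try:
            half_life = float(row["half_life_h"])
            energy = float(row["energy"]) * scale
            yield_ = float(row["yield"])
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}:{lineno}: non-numeric half_life/energy/yield in row {row!r}"
            ) from None
        rtype = (row.get("radiation_type") or "").strip()
        spectrum = str(row.get("spectrum_bin", "")).strip().lower() in ("1", "true", "yes")
        try:
            emission = RadiationEmission(rtype, energy, yield_, spectrum_bin=spectrum)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
        dup_key = (name, rtype, energy, yield_)
        if dup_key in seen_rows:
            warnings.warn(
                f"{path}:{lineno}: duplicate emission row for {name!r} kept",
                stacklevel=2,
            )
        seen_rows.add(dup_key)
        rec = per_nuclide.setdefault(name, {"half_life_h": half_life, "emissions": []})
        if not math.isclose(rec["half_life_h"], half_life, rel_tol=1e-9):
            raise FormatError(
                f"{path}:{lineno}: inconsistent half-life for {name!r}: "
                f"{rec['half_life_h']} vs {half_life}"
            )
        rec["emissions"].append(emission)

    if not per_nuclide:
        raise FormatError(f"{path}: no emission rows")
    return [
        Nuclide(name, rec["half_life_h"], tuple(rec["emissions"]))
        for name, rec in per_nuclide.items()
    ]
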