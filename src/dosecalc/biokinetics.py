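"""Biokinetics: time-integrated activity (TIA) per source region.

A biokinetic model maps source regions to time–activity descriptions
(sums of exponentials whose rates include physical decay, or directly
tabulated cumulated activities) and optionally carries special entries
handled by dedicated rules:

* urinary excretion — bladder filling with periodic voiding,
* gastrointestinal excretion — first-order catenary transit through the
  alimentary-tract segments,
* legacy gut regions — conversion of upper/lower large intestine TIA to
  the right/left/rectosigmoid colon segments by fixed mass-based factors,
* bone seekers — surface vs volume deposition by effective half-time,
* circulating blood — distribution over regions by fractional blood
  content,
* "other organs and tissues" — the total-body TIA minus the explicitly
  accounted organs.

All TIAs are in hours (Bq·h per Bq administered).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .catalog import (
    LEGACY_LLI,
    LEGACY_ULI,
    OTHER_TISSUES,
    TOTAL_BODY,
    normalize_region,
)
from .errors import FormatError
from .phantom import Phantom

logger = logging.getLogger(__name__)

# Colon conversion factors (mass-based reassignment of the legacy gut
# regions onto the alimentary-tract colon segments).
RIGHT_COLON_FROM_ULI = 0.71
LEFT_COLON_FROM_ULI = 0.29
LEFT_COLON_FROM_LLI = 0.56
RECTOSIGMOID_FROM_LLI = 0.44

#: Bone seekers with effective half-time shorter than this are
#: surface-deposited; at or above it, volume-deposited.
BONE_SURFACE_HALF_TIME_DAYS = 15.0

#: 1/ln2 — converts a half-time into the integral of pure decay.
INV_LN2 = 1.0 / math.log(2.0)

#: Default standardized voiding interval (hours); a configuration
#: default, overridable everywhere it is consumed.
DEFAULT_VOIDING_INTERVAL_H = 3.5

#: Default first-order catenary transit chain for GI-excreted activity:
#: segment content regions and mean residence times (hours).  These are
#: fixture defaults in the spirit of the alimentary-tract model, not a
#: reference tabulation.
DEFAULT_GI_SEGMENTS = (
    "stomach contents",
    "small intestine contents",
    "right colon contents",
    "left colon contents",
    "rectosigmoid colon contents",
)
DEFAULT_GI_RESIDENCE_H = (0.75, 4.0, 12.0, 12.0, 12.0)

_BONE_SURFACES = ("trabecular bone surface", "cortical bone surface")
_BONE_VOLUMES = ("trabecular bone volume", "cortical bone volume")


@dataclass(frozen=True)
class TimeActivityFunction:
    """Either a sum of exponentials A(t) = Σ c_k·e^(−λ_k·t) or a stored TIA.

    For exponential sums, the rates λ_k (h⁻¹) must already include
    physical decay; coefficients are fractions of the administered
    activity A₀.
    """

    form: str  # exponential_sum | tabulated_tia
    terms: tuple[tuple[float, float], ...] = ()
    tia_hours: float | None = None

    def __post_init__(self):
        if self.form == "exponential_sum":
            object.__setattr__(self, "terms", tuple((float(c), float(r)) for c, r in self.terms))
            if not self.terms:
                raise ValueError("exponential_sum needs at least one (coefficient, rate) term")
            for c, rate in self.terms:
                if not rate > 0:
                    raise ValueError(f"exponential rate must be > 0, got {rate}")
        elif self.form == "tabulated_tia":
            if self.tia_hours is None or self.tia_hours < 0:
                raise ValueError(f"tabulated TIA must be >= 0, got {self.tia_hours}")
        else:
            raise ValueError(f"unknown time-activity form {self.form!r}")

    def __call__(self, t: float) -> float:
        if self.form != "exponential_sum":
            raise ValueError("only exponential_sum functions are evaluable in time")
        return sum(c * math.exp(-rate * t) for c, rate in self.terms)

    @classmethod
    def from_dict(cls, data: dict) -> "TimeActivityFunction":
        form = data.get("form")
        if form == "exponential_sum":
            return cls(form=form, terms=tuple((c, r) for c, r in data["terms"]))
        if form == "tabulated_tia":
            return cls(form=form, tia_hours=float(data["hours"]))
        raise FormatError(f"unknown time-activity form {form!r}")


@dataclass
class BiokineticModel:
    """Parsed biokinetic model for one radiopharmaceutical."""

    nuclide: str
    entries: dict[str, TimeActivityFunction] = field(default_factory=dict)
    urine_input: TimeActivityFunction | None = None
    gi_input: dict | None = None
    bone_entry: dict | None = None  # {"tia_h":, "t_eff_days":, "split"?:}
    blood_tia_h: float | None = None
    half_life_h: float | None = None


def load_model(path: str | Path) -> BiokineticModel:
    """Load a biokinetic-model JSON/YAML file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    try:
        entries = {
            normalize_region(region): TimeActivityFunction.from_dict(f)
            for region, f in (data.get("entries") or {}).items()
        }
        model = BiokineticModel(
            nuclide=data["nuclide"],
            entries=entries,
            urine_input=(
                TimeActivityFunction.from_dict(data["urine_input"])
                if data.get("urine_input") else None
            ),
            gi_input=data.get("gi_input"),
            bone_entry=data.get("bone_entry"),
            blood_tia_h=data.get("blood_tia_h"),
            half_life_h=data.get("half_life_h"),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise FormatError(f"{path}: {exc}") from None
    if model.bone_entry is not None and not float(model.bone_entry["t_eff_days"]) > 0:
        raise FormatError(f"{path}: bone effective half-time must be > 0")
    return model


@dataclass
class TIAVector:
    """TIA per source region (hours) with a record of the rules applied."""

    entries: dict[str, float] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)

    def add(self, region: str, tia: float, rule: str) -> None:
        region = normalize_region(region)
        if tia < 0:
            raise ValueError(f"negative TIA {tia} for {region!r}")
        if region in self.entries and self.entries[region] != 0.0:
            logger.info("region %r fed by multiple rules; TIAs summed", region)
        self.entries[region] = self.entries.get(region, 0.0) + tia
        self.provenance.append(f"{rule}: {region} += {tia:.6e} h")

    def total(self) -> float:
        return sum(self.entries.values())

    def validate(self, physical_half_life_h: float, rel_tol: float = 1e-9) -> None:
        """No model may exceed pure physical decay of all administered activity."""
        bound = INV_LN2 * physical_half_life_h
        if self.total() > bound * (1.0 + rel_tol):
            raise ValueError(
                f"total TIA {self.total():g} h exceeds the physical-decay bound "
                f"{bound:g} h (= T_phys/ln2)"
            )


def integrate_time_activity(f: TimeActivityFunction, t_d: float = math.inf) -> float:
    """∫₀^T_D A(t) dt in hours; closed form for exponential sums.

    Tabulated TIAs return the stored value (the horizon is ignored with
    a log note, since the tabulation fixed its own horizon).
    """
    if f.form == "tabulated_tia":
        if t_d != math.inf:
            logger.info("tabulated TIA: integration horizon %s ignored", t_d)
        return float(f.tia_hours)
    total = 0.0
    for c, rate in f.terms:
        if t_d == math.inf:
            total += c / rate
        else:
            total += c * (-math.expm1(-rate * t_d)) / rate
    return total


def bladder_tia(
    urine_input: TimeActivityFunction,
    voiding_interval_h: float,
    physical_rate_per_h: float,
    rel_tol: float = 1e-12,
) -> float:
    """TIA of the urinary bladder contents under periodic voiding.

    ``urine_input`` is the bladder content curve in the absence of
    voiding (rates include physical decay).  The bladder is emptied
    instantaneously at every multiple of the voiding interval; between
    voids the standing content changes only by inflow and physical
    decay, so content removed at a void would subsequently have decayed
    purely physically.  Hence

        TIA = ∫₀^∞ f(t) dt − Σ_v B(t_v⁻)/λ_phys,

    with the pre-void contents B(t_v⁻) obtained recursively.  Cycles are
    accumulated until the relative contribution falls below ``rel_tol``.
    """
    if not voiding_interval_h > 0:
        raise ValueError(f"voiding interval must be > 0, got {voiding_interval_h}")
    if urine_input.form != "exponential_sum":
        raise ValueError("bladder voiding requires an exponential_sum inflow description")
    if not physical_rate_per_h > 0:
        raise ValueError(
            f"physical decay rate must be > 0 for bladder accumulation, "
            f"got {physical_rate_per_h}"
        )
    no_void_total = integrate_time_activity(urine_input, math.inf)
    if voiding_interval_h == math.inf:
        return no_void_total
    lam = physical_rate_per_h
    decay_per_cycle = math.exp(-lam * voiding_interval_h)
    removed_virtual = 0.0  # removed content propagated to the current void time
    deduction = 0.0
    scale = max(no_void_total, 1e-300)
    n = 1
    while True:
        t_v = n * voiding_interval_h
        f_t = urine_input(t_v)
        removed_virtual *= decay_per_cycle
        pre_void = f_t - removed_virtual
        if pre_void > 0.0:
            deduction += pre_void / lam
            removed_virtual += pre_void
        # once the un-voided curve itself is negligible, later voids are too
        if f_t / lam < rel_tol * scale or n > 10_000_000:
            break
        n += 1
    return max(no_void_total - deduction, 0.0)


def colon_convert(tia_uli: float, tia_lli: float) -> tuple[float, float, float]:
    """Reassign legacy upper/lower large-intestine TIA to the colon segments.

    right = 0.71·ULI; left = 0.29·ULI + 0.56·LLI; rectosigmoid = 0.44·LLI.
    The factors are mass-based and conserve activity exactly.
    """
    if tia_uli < 0 or tia_lli < 0:
        raise ValueError("legacy intestine TIA must be >= 0")
    right = RIGHT_COLON_FROM_ULI * tia_uli
    left = LEFT_COLON_FROM_ULI * tia_uli + LEFT_COLON_FROM_LLI * tia_lli
    recto = RECTOSIGMOID_FROM_LLI * tia_lli
    return right, left, recto


def bone_partition(
    tia_bone_h: float,
    effective_half_time_days: float,
    known_split: dict[str, float] | None = None,
    phantom: Phantom | None = None,
    surface_fractions: tuple[float, float] = (0.5, 0.5),
) -> dict[str, float]:
    """Partition a skeletal TIA over the four bone compartments.

    With an explicitly known split it is applied verbatim.  Otherwise
    substances with effective half-time shorter than 15 days deposit on
    bone surfaces, and at 15 days or longer uniformly throughout the
    trabecular and cortical bone volume.  Surface TIA splits
    trabecular/cortical by ``surface_fractions`` (default 50/50); volume
    TIA splits mass-proportionally when a phantom is given, else 50/50.
    """
    if tia_bone_h < 0:
        raise ValueError("bone TIA must be >= 0")
    if known_split is not None:
        total_frac = sum(known_split.values())
        if not math.isclose(total_frac, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"known bone split fractions sum to {total_frac}, expected 1")
        return {normalize_region(k): tia_bone_h * v for k, v in known_split.items()}
    out = {c: 0.0 for c in _BONE_SURFACES + _BONE_VOLUMES}
    if effective_half_time_days < BONE_SURFACE_HALF_TIME_DAYS:
        f_trab, f_cort = surface_fractions
        if not math.isclose(f_trab + f_cort, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("surface fractions must sum to 1")
        out["trabecular bone surface"] = tia_bone_h * f_trab
        out["cortical bone surface"] = tia_bone_h * f_cort
    else:
        if phantom is not None and all(phantom.has_region(r) for r in _BONE_VOLUMES):
            m_trab = phantom.mass("trabecular bone volume")
            m_cort = phantom.mass("cortical bone volume")
            f_trab = m_trab / (m_trab + m_cort)
        else:
            f_trab = 0.5
        out["trabecular bone volume"] = tia_bone_h * f_trab
        out["cortical bone volume"] = tia_bone_h * (1.0 - f_trab)
    return out


def distribute_blood(
    blood_tia_h: float, phantom: Phantom
) -> tuple[dict[str, float], float]:
    """Distribute circulating-blood TIA over regions by blood content.

    Returns (per-region TIA, unassigned residue).  The residue — blood
    in tissues without an explicit blood fraction — belongs to the
    "other organs and tissues" pool.
    """
    if blood_tia_h < 0:
        raise ValueError("blood TIA must be >= 0")
    fractions = phantom.blood_fractions()
    if not fractions:
        raise ValueError(f"{phantom.sex} phantom defines no blood-content fractions")
    out = {region: blood_tia_h * frac for region, frac in fractions.items()}
    residue = blood_tia_h * (1.0 - sum(fractions.values()))
    return out, max(residue, 0.0)


def gi_transit_tia(
    amount: float,
    residence_times_h: tuple[float, ...],
    physical_rate_per_h: float,
) -> list[float]:
    """Per-segment TIA for a bolus traversing a first-order catenary chain.

    With transfer rates k_i = 1/MRT_i and physical decay λ, the fraction
    reaching segment i is Π_{j<i} k_j/(k_j+λ), and each unit entering
    contributes 1/(k_i+λ) hours of TIA there.
    """
    if amount < 0:
        raise ValueError("entering amount must be >= 0")
    if not physical_rate_per_h > 0:
        raise ValueError("physical decay rate must be > 0")
    tias = []
    reaching = amount
    for mrt in residence_times_h:
        if not mrt > 0:
            raise ValueError(f"mean residence time must be > 0, got {mrt}")
        k = 1.0 / mrt
        tias.append(reaching / (k + physical_rate_per_h))
        reaching *= k / (k + physical_rate_per_h)
    return tias


def resolve_model(
    model: BiokineticModel,
    phantom: Phantom,
    t_d: float = math.inf,
    voiding_interval_h: float = DEFAULT_VOIDING_INTERVAL_H,
    physical_half_life_h: float | None = None,
) -> TIAVector:
    """Assemble the per-region TIA vector, applying every adjustment rule.

    Order: entry integration, bladder voiding, GI transit, legacy-colon
    conversion, bone partition, blood distribution; finally the residual
    rule replaces a total-body entry with "other organs and tissues" =
    total body − Σ explicit organs (floored at 0 with a warning).
    """
    half_life = physical_half_life_h or model.half_life_h
    lam_phys = math.log(2.0) / half_life if half_life else None
    vec = TIAVector()

    legacy_uli = 0.0
    legacy_lli = 0.0
    for region, f in model.entries.items():
        tia = integrate_time_activity(f, t_d)
        if region == LEGACY_ULI:
            legacy_uli += tia
        elif region == LEGACY_LLI:
            legacy_lli += tia
        else:
            vec.add(region, tia, "integration")

    if model.urine_input is not None:
        if lam_phys is None:
            raise ValueError("bladder voiding requires the physical half-life")
        tia = bladder_tia(model.urine_input, voiding_interval_h, lam_phys)
        vec.add("urinary bladder contents", tia, f"bladder voiding (interval {voiding_interval_h} h)")

    if model.gi_input is not None:
        if lam_phys is None:
            raise ValueError("GI transit requires the physical half-life")
        segments = tuple(model.gi_input.get("segments", DEFAULT_GI_SEGMENTS))
        residence = tuple(model.gi_input.get("mean_residence_h", DEFAULT_GI_RESIDENCE_H))
        if len(segments) != len(residence):
            raise FormatError("gi_input: segments and mean_residence_h differ in length")
        amount = float(model.gi_input.get("amount", 1.0))
        for segment, tia in zip(segments, gi_transit_tia(amount, residence, lam_phys)):
            vec.add(segment, tia, "GI transit")

    if legacy_uli or legacy_lli:
        right, left, recto = colon_convert(legacy_uli, legacy_lli)
        vec.add("right colon wall", right, "colon conversion")
        vec.add("left colon wall", left, "colon conversion")
        vec.add("rectosigmoid colon wall", recto, "colon conversion")

    if model.bone_entry is not None:
        parts = bone_partition(
            float(model.bone_entry["tia_h"]),
            float(model.bone_entry["t_eff_days"]),
            known_split=model.bone_entry.get("split"),
            phantom=phantom,
        )
        for compartment, tia in parts.items():
            if tia > 0.0:
                vec.add(compartment, tia, "bone partition")

    blood_residue = 0.0
    if model.blood_tia_h is not None:
        dist, blood_residue = distribute_blood(float(model.blood_tia_h), phantom)
        for region, tia in dist.items():
            if tia > 0.0:
                vec.add(region, tia, "blood distribution")

    if TOTAL_BODY in vec.entries:
        tb = vec.entries.pop(TOTAL_BODY)
        explicit = sum(vec.entries.values())
        residual = tb - explicit
        if residual < 0.0:
            logger.warning(
                "negative residual TIA %.3e h (total body %.3e < explicit organs %.3e); "
                "floored at 0", residual, tb, explicit,
            )
            residual = 0.0
        vec.add(OTHER_TISSUES, residual + blood_residue, "other-tissues residual")
    elif blood_residue > 0.0:
        vec.add(OTHER_TISSUES, blood_residue, "blood residue")

    if half_life is not None:
        vec.validate(half_life)
    return vec
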