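"""Effective dose: tissue weighting and sex averaging, E = Σ_T w_T Σ_R w_R D_R.

Two packaged weighting schemes are provided.

* The 2007 scheme (ICRP 103): the remainder weight (0.12) is divided
  equally among 13 specified tissues per sex; equivalent doses for the
  reference male and female are weighted separately and then averaged
  to give the reference-person value, so E_ref is exactly the
  arithmetic mean of the single-sex values.
* The 1990 scheme (ICRP 60): tissue weights are applied to organ doses
  averaged between the sexes; the remainder (0.05) takes the
  mass-weighted mean dose over a configurable remainder list, with a
  splitting rule — if a single remainder tissue receives a higher dose
  than every named tissue, half the remainder weight applies to that
  tissue and half to the mass-weighted mean of the rest.

w_R = 1 for every radiation type in diagnostic use, so equivalent dose
equals absorbed dose numerically (mSv/MBq vs mGy/MBq); the breakdown
keeps both labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from .catalog import normalize_region
from .dose import DoseCoefficientResult, colon_target_dose
from .phantom import Phantom

#: tissues whose dose comes from a different organ per sex
SEX_SPECIFIC = {
    "gonads": {"male": "testes", "female": "ovaries"},
    "prostate": {"male": "prostate", "female": None},
    "uterus": {"male": None, "female": "uterus"},
}

_ICRP103_WEIGHTS = {
    "red marrow": "0.12",
    "colon": "0.12",
    "lungs": "0.12",
    "stomach wall": "0.12",
    "breast": "0.12",
    "gonads": "0.08",
    "urinary bladder wall": "0.04",
    "oesophagus": "0.04",
    "liver": "0.04",
    "thyroid": "0.04",
    "bone surface": "0.01",
    "brain": "0.01",
    "salivary glands": "0.01",
    "skin": "0.01",
}
_ICRP103_REMAINDER_WEIGHT = "0.12"
#: the 13 remainder tissues; the sex-specific slot is prostate (male) /
#: uterus (female)
_ICRP103_REMAINDER = (
    "adrenals",
    "extrathoracic region",
    "gall bladder wall",
    "heart wall",
    "kidneys",
    "lymphatic nodes",
    "muscle",
    "oral mucosa",
    "pancreas",
    "prostate",  # uterus for the female list
    "small intestine wall",
    "spleen",
    "thymus",
)

_ICRP60_WEIGHTS = {
    "gonads": "0.20",
    "red marrow": "0.12",
    "colon": "0.12",
    "lungs": "0.12",
    "stomach wall": "0.12",
    "urinary bladder wall": "0.05",
    "breast": "0.05",
    "liver": "0.05",
    "oesophagus": "0.05",
    "thyroid": "0.05",
    "skin": "0.01",
    "bone surface": "0.01",
}
_ICRP60_REMAINDER_WEIGHT = "0.05"
_ICRP60_REMAINDER = (
    "adrenals",
    "brain",
    "small intestine wall",
    "kidneys",
    "muscle",
    "pancreas",
    "spleen",
    "thymus",
    "uterus",
    "upper large intestine",
)


@dataclass(frozen=True)
class WeightingScheme:
    """A tissue-weighting scheme: named weights plus a remainder rule."""

    scheme_id: str
    weights: dict[str, float]
    remainder_weight: float
    remainder_male: tuple[str, ...]
    remainder_female: tuple[str, ...]
    remainder_rule: str  # mass_weighted_with_splitting | arithmetic_mean_13

    def remainder_tissues(self, sex: str) -> tuple[str, ...]:
        return self.remainder_male if sex == "male" else self.remainder_female


def _validated(scheme: WeightingScheme, fractions: list[Fraction]) -> WeightingScheme:
    total = sum(fractions, Fraction(0))
    if total != 1:
        raise ValueError(f"{scheme.scheme_id}: tissue weights sum to {total}, expected 1")
    if set(scheme.remainder_male) & set(scheme.weights) or set(scheme.remainder_female) & set(scheme.weights):
        raise ValueError(f"{scheme.scheme_id}: remainder tissues overlap named tissues")
    return scheme


def load_weighting_scheme(
    scheme_id: str, remainder_override: tuple[str, ...] | None = None
) -> WeightingScheme:
    """Return a packaged weighting scheme ('ICRP60' or 'ICRP103').

    The 1990 remainder tissue list is configurable via
    ``remainder_override``; weights themselves are fixed and validated
    to sum to exactly 1 in exact decimal arithmetic.
    """
    if scheme_id == "ICRP103":
        weights = {t: float(w) for t, w in _ICRP103_WEIGHTS.items()}
        remainder_f = tuple(
            "uterus" if t == "prostate" else t for t in _ICRP103_REMAINDER
        )
        scheme = WeightingScheme(
            scheme_id="ICRP103",
            weights=weights,
            remainder_weight=float(_ICRP103_REMAINDER_WEIGHT),
            remainder_male=_ICRP103_REMAINDER,
            remainder_female=remainder_f,
            remainder_rule="arithmetic_mean_13",
        )
        fractions = [Fraction(w) for w in _ICRP103_WEIGHTS.values()]
        fractions.append(Fraction(_ICRP103_REMAINDER_WEIGHT))
        return _validated(scheme, fractions)
    if scheme_id == "ICRP60":
        remainder = tuple(remainder_override) if remainder_override else _ICRP60_REMAINDER
        scheme = WeightingScheme(
            scheme_id="ICRP60",
            weights={t: float(w) for t, w in _ICRP60_WEIGHTS.items()},
            remainder_weight=float(_ICRP60_REMAINDER_WEIGHT),
            remainder_male=remainder,
            remainder_female=remainder,
            remainder_rule="mass_weighted_with_splitting",
        )
        fractions = [Fraction(w) for w in _ICRP60_WEIGHTS.values()]
        fractions.append(Fraction(_ICRP60_REMAINDER_WEIGHT))
        return _validated(scheme, fractions)
    raise ValueError(f"unknown weighting scheme {scheme_id!r}")


@dataclass
class RemainderResult:
    """Outcome of the 1990 remainder rule."""

    dose_term: float  # effective dose term per unit remainder weight
    splitting: bool
    dominant: str | None = None


def remainder_dose_icrp60(
    remainder_doses: dict[str, float],
    remainder_masses: dict[str, float],
    max_named_dose: float,
) -> RemainderResult:
    """Remainder equivalent-dose term under the 1990 scheme.

    Default: mass-weighted mean dose over the remainder tissues.  If the
    highest-dosed remainder tissue exceeds every named-tissue dose, the
    splitting rule fires: half the remainder weight goes to that tissue,
    half to the mass-weighted mean of the remaining remainder tissues.
    """
    if not remainder_doses:
        raise ValueError("empty remainder tissue list")
    keys = list(remainder_doses)
    masses = {k: remainder_masses.get(k, 1.0) for k in keys}

    def mass_mean(subset):
        m = sum(masses[k] for k in subset)
        if m == 0.0:
            return 0.0
        return sum(masses[k] * remainder_doses[k] for k in subset) / m

    dominant = max(keys, key=lambda k: remainder_doses[k])
    if remainder_doses[dominant] > max_named_dose:
        rest = [k for k in keys if k != dominant]
        rest_term = mass_mean(rest) if rest else remainder_doses[dominant]
        return RemainderResult(
            dose_term=0.5 * remainder_doses[dominant] + 0.5 * rest_term,
            splitting=True,
            dominant=dominant,
        )
    return RemainderResult(dose_term=mass_mean(keys), splitting=False)


@dataclass
class EffectiveDoseResult:
    """E/A₀ per scheme: reference person plus single-sex values, mSv/MBq."""

    scheme_id: str
    e_ref: float
    e_male: float
    e_female: float
    breakdown: dict[str, dict] = field(default_factory=dict)


def _dose_table(doses) -> dict[str, float]:
    return {normalize_region(k): v for k, v in dict(getattr(doses, "doses", doses)).items()}


def _tissue_dose(
    table: dict[str, float], tissue: str, sex: str, phantom: Phantom | None
) -> float | None:
    """Equivalent dose for a scheme tissue from one sex's dose table.

    Handles the sex-specific organs (gonads → testes/ovaries,
    prostate/uterus) and the composite colon target (direct entry if
    present, else the mass-weighted segment mean).  Returns None when
    the tissue does not exist for this sex.
    """
    tissue = normalize_region(tissue)
    if tissue in SEX_SPECIFIC:
        organ = SEX_SPECIFIC[tissue][sex]
        if organ is None:
            # absent for this sex; a pre-averaged table may still carry it
            return table.get(tissue)
        return table.get(normalize_region(organ), table.get(tissue))
    if tissue == "colon" and tissue not in table:
        if phantom is None:
            return None
        try:
            return colon_target_dose(table, phantom)
        except KeyError:
            return None
    return table.get(tissue)


def _remainder_mean(table, tissues, sex, phantom) -> float:
    """Arithmetic mean over the remainder tissues available for this sex."""
    values = []
    for t in tissues:
        h = _tissue_dose(table, t, sex, phantom)
        if h is not None:
            values.append(h)
    if not values:
        raise ValueError("no remainder tissue has a dose value")
    return sum(values) / len(values)


def effective_dose_icrp103(
    doses_male: DoseCoefficientResult | dict,
    doses_female: DoseCoefficientResult | dict,
    scheme: WeightingScheme | None = None,
    phantom_male: Phantom | None = None,
    phantom_female: Phantom | None = None,
) -> EffectiveDoseResult:
    """Effective dose under the 2007 scheme.

    Each sex's equivalent doses are weighted separately and the
    reference-person value is the arithmetic mean of the two.  A tissue
    present in only one sex contributes that sex's dose to both
    single-sex values (standard reference-person construction); a tissue
    missing from both sexes is an error.
    """
    scheme = scheme or load_weighting_scheme("ICRP103")
    tm = _dose_table(doses_male)
    tf = _dose_table(doses_female)
    e_male = 0.0
    e_female = 0.0
    breakdown: dict[str, dict] = {}
    for tissue, w in scheme.weights.items():
        hm = _tissue_dose(tm, tissue, "male", phantom_male)
        hf = _tissue_dose(tf, tissue, "female", phantom_female)
        if hm is None and hf is None:
            raise ValueError(f"tissue {tissue!r} missing from both sexes' dose tables")
        am = hm if hm is not None else hf
        af = hf if hf is not None else hm
        e_male += w * am
        e_female += w * af
        breakdown[tissue] = {"w_T": w, "H_male_mSv_per_MBq": am, "H_female_mSv_per_MBq": af}
    rm = _remainder_mean(tm, scheme.remainder_tissues("male"), "male", phantom_male)
    rf = _remainder_mean(tf, scheme.remainder_tissues("female"), "female", phantom_female)
    e_male += scheme.remainder_weight * rm
    e_female += scheme.remainder_weight * rf
    breakdown["remainder"] = {
        "w_T": scheme.remainder_weight,
        "H_male_mSv_per_MBq": rm,
        "H_female_mSv_per_MBq": rf,
    }
    return EffectiveDoseResult(
        scheme_id=scheme.scheme_id,
        e_ref=0.5 * (e_male + e_female),
        e_male=e_male,
        e_female=e_female,
        breakdown=breakdown,
    )


def _icrp60_single(table, sex, scheme, phantom, masses) -> tuple[float, RemainderResult]:
    named = {}
    for tissue, w in scheme.weights.items():
        h = _tissue_dose(table, tissue, sex, phantom)
        if h is None:
            raise ValueError(f"tissue {tissue!r} missing from {sex} dose table")
        named[tissue] = h
    rem_doses = {}
    for t in scheme.remainder_tissues(sex):
        h = _tissue_dose(table, t, sex, phantom)
        if h is not None:
            rem_doses[normalize_region(t)] = h
    if not rem_doses:
        raise ValueError("no remainder tissue has a dose value")
    rem = remainder_dose_icrp60(rem_doses, masses, max(named.values()))
    e = sum(scheme.weights[t] * named[t] for t in named)
    e += scheme.remainder_weight * rem.dose_term
    return e, rem


def effective_dose_icrp60(
    doses_male: DoseCoefficientResult | dict,
    doses_female: DoseCoefficientResult | dict,
    scheme: WeightingScheme | None = None,
    phantom_male: Phantom | None = None,
    phantom_female: Phantom | None = None,
) -> EffectiveDoseResult:
    """Effective dose under the 1990 scheme.

    Organ doses are first averaged between the sexes (a tissue present
    in one sex only contributes that sex's dose), then the 1990 weights
    and the mass-weighted remainder rule are applied.  Single-sex values
    apply the same weights to each sex's own dose table.
    """
    scheme = scheme or load_weighting_scheme("ICRP60")
    tm = _dose_table(doses_male)
    tf = _dose_table(doses_female)

    def masses_for(tissues) -> dict[str, float]:
        out = {}
        for t in tissues:
            key = normalize_region(t)
            vals = []
            for phantom, sex in ((phantom_male, "male"), (phantom_female, "female")):
                organ = SEX_SPECIFIC.get(key, {}).get(sex, key) if key in SEX_SPECIFIC else key
                if phantom is not None and organ and phantom.has_region(organ):
                    vals.append(phantom.mass(organ))
            out[key] = sum(vals) / len(vals) if vals else 1.0
        return out

    # sex-averaged tissue table covering named + remainder tissues
    avg: dict[str, float] = {}
    all_tissues = list(scheme.weights) + list(
        dict.fromkeys(scheme.remainder_male + scheme.remainder_female)
    )
    for tissue in all_tissues:
        hm = _tissue_dose(tm, tissue, "male", phantom_male)
        hf = _tissue_dose(tf, tissue, "female", phantom_female)
        if hm is None and hf is None:
            if tissue in scheme.weights:
                raise ValueError(f"tissue {tissue!r} missing from both sexes' dose tables")
            continue
        both = [h for h in (hm, hf) if h is not None]
        avg[normalize_region(tissue)] = sum(both) / len(both)

    masses = masses_for(avg)
    e_ref, rem = _icrp60_single(avg, "male", scheme, None, masses)
    # the averaged table already resolved sex-specific organs, so the
    # sex argument above is inert; single-sex values use each sex's table
    e_male, rem_m = _icrp60_single(tm, "male", scheme, phantom_male, masses)
    e_female, rem_f = _icrp60_single(tf, "female", scheme, phantom_female, masses)
    breakdown = {
        tissue: {"w_T": w, "H_avg_mSv_per_MBq": avg.get(tissue)}
        for tissue, w in scheme.weights.items()
    }
    breakdown["remainder"] = {
        "w_T": scheme.remainder_weight,
        "H_avg_mSv_per_MBq": rem.dose_term,
        "splitting": rem.splitting,
        "dominant": rem.dominant,
    }
    return EffectiveDoseResult(
        scheme_id=scheme.scheme_id,
        e_ref=e_ref,
        e_male=e_male,
        e_female=e_female,
        breakdown=breakdown,
    )
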