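"""Synthetic, self-consistent fixture data for the whole dose chain.

Generates nuclides, phantoms, SAF tables and biokinetic models that are
physically plausible in magnitude (masses 0.01–70 kg, SAFs bounded by
energy conservation, half-lives 0.1 h–100 d) without emulating any
reference compilation's actual values.  Every file round-trips through
the package's public readers.

The SAF construction enforces the energy balance
Σ_targets φ(T ← S, E) ≤ 1 per source and energy by drawing normalized
target shares under a budget, and builds the "total body" source rows
as the mass-weighted combination of all per-source rows so that the
remainder-formula identity holds exactly on fixtures.

Also hosts :func:`oracle_dose`, a deliberately naive nested-loop
reimplementation of the dose computation (own file parsing, own
interpolation, own integration) used as the independent cross-check of
the main engine.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nucleardata import Nuclide, RadiationEmission

# ordered (name, male mass kg, female mass kg); the first block is the
# required core (alimentary segments, bladder pair)
_CORE_REGIONS = [
    ("oral cavity", 0.046, 0.041),
    ("oesophagus", 0.040, 0.035),
    ("stomach wall", 0.150, 0.140),
    ("stomach contents", 0.250, 0.230),
    ("small intestine wall", 0.650, 0.600),
    ("small intestine contents", 0.350, 0.280),
    ("right colon wall", 0.150, 0.145),
    ("right colon contents", 0.150, 0.160),
    ("left colon wall", 0.150, 0.145),
    ("left colon contents", 0.075, 0.080),
    ("rectosigmoid colon wall", 0.070, 0.070),
    ("rectosigmoid colon contents", 0.075, 0.080),
    ("urinary bladder wall", 0.050, 0.040),
    ("urinary bladder contents", 0.200, 0.200),
]

_EXTRA_REGIONS = [
    ("liver", 1.80, 1.40),
    ("kidneys", 0.310, 0.275),
    ("spleen", 0.150, 0.130),
    ("lungs", 1.20, 0.95),
    ("muscle", 29.0, 17.5),
    ("red marrow", 1.17, 0.90),
    ("brain", 1.45, 1.30),
    ("heart wall", 0.330, 0.250),
    ("heart contents", 0.510, 0.370),
    ("trabecular bone surface", 0.006, 0.005),
    ("cortical bone surface", 0.006, 0.005),
    ("trabecular bone volume", 1.10, 0.90),
    ("cortical bone volume", 4.40, 3.20),
    ("pancreas", 0.140, 0.120),
    ("thyroid", 0.020, 0.017),
    ("skin", 3.30, 2.30),
    ("breast", 0.025, 0.500),
    ("adrenals", 0.014, 0.013),
    ("thymus", 0.025, 0.020),
    ("bone surface", 0.012, 0.010),
    ("salivary glands", 0.085, 0.070),
    ("oral mucosa", 0.020, 0.018),
    ("extrathoracic region", 0.015, 0.013),
    ("lymphatic nodes", 0.150, 0.130),
    ("gall bladder wall", 0.010, 0.008),
]

_SEX_REGIONS = {
    "male": [("testes", 0.035), ("prostate", 0.017)],
    "female": [("ovaries", 0.011), ("uterus", 0.080)],
}

_BLOOD_FRACTIONS = {
    "liver": 0.10,
    "lungs": 0.105,
    "kidneys": 0.02,
    "spleen": 0.014,
    "heart contents": 0.09,
    "muscle": 0.14,
    "brain": 0.012,
    "red marrow": 0.04,
}

_MIN_REGIONS = len(_CORE_REGIONS)


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs for the synthetic corpus; the same seed yields identical bytes."""

    seed: int = 0
    n_regions: int | None = None  # None → full region set
    energy_grid: tuple[float, ...] = (0.01, 0.03, 0.1, 0.3, 1.0)
    n_emissions: int = 4
    energy_range: tuple[float, float] = (0.02, 2.0)
    yield_range: tuple[float, float] = (0.05, 1.0)
    phi_budget: float = 0.9  # energy-balance budget Σ_T φ ≤ this
    half_life_range_h: tuple[float, float] = (1.0, 240.0)
    nuclide_name: str = "Xx-199"

    def __post_init__(self):
        if self.n_regions is not None and self.n_regions < _MIN_REGIONS:
            raise ValueError(
                f"n_regions must be >= {_MIN_REGIONS} (alimentary segments, "
                f"bladder pair), got {self.n_regions}"
            )
        if not 0.0 < self.phi_budget <= 1.0:
            raise ValueError("phi_budget must be in (0, 1]")


def _rng(spec: FixtureSpec, salt: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, salt])


def _fmt(x: float) -> str:
    return f"{float(x):.10g}"


# ----------------------------------------------------------------- nuclide

def make_toy_nuclide(spec: FixtureSpec) -> Nuclide:
    """A synthetic photon/electron emitter with seeded emission lines."""
    rng = _rng(spec, 1)
    lo, hi = spec.half_life_range_h
    half_life = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    emissions = []
    e_lo, e_hi = spec.energy_range
    y_lo, y_hi = spec.yield_range
    for i in range(spec.n_emissions):
        rtype = "photon" if i % 2 == 0 else "electron"
        energy = float(np.exp(rng.uniform(np.log(e_lo), np.log(e_hi))))
        yld = float(rng.uniform(y_lo, y_hi))
        emissions.append(RadiationEmission(rtype, energy, yld))
    return Nuclide(spec.nuclide_name, half_life, tuple(emissions))


def write_decay_file(path: str | Path, nuclides: list[Nuclide],
                     energy_unit: str = "MeV") -> None:
    """Write nuclides in the decay-CSV dialect (inverse of the parser)."""
    if energy_unit not in ("MeV", "keV"):
        raise ValueError(f"energy unit must be MeV or keV, got {energy_unit!r}")
    scale = 1.0 if energy_unit == "MeV" else 1e3
    lines = [f"# energy_unit={energy_unit}",
             "nuclide,half_life_h,radiation_type,energy,yield,spectrum_bin"]
    for nuc in nuclides:
        for e in nuc.emissions:
            lines.append(
                f"{nuc.name},{_fmt(nuc.half_life_h)},{e.radiation_type},"
                f"{_fmt(e.energy_mev * scale)},{_fmt(e.yield_per_decay)},"
                f"{int(e.spectrum_bin)}"
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ----------------------------------------------------------------- phantom

def _region_rows(spec: FixtureSpec, sex: str, rng) -> list[dict]:
    n_extra = (len(_EXTRA_REGIONS) if spec.n_regions is None
               else min(spec.n_regions - _MIN_REGIONS, len(_EXTRA_REGIONS)))
    chosen = _CORE_REGIONS + _EXTRA_REGIONS[:n_extra]
    col = 1 if sex == "male" else 2
    rows = []
    for rec in chosen:
        name, mass = rec[0], rec[col]
        mass = float(mass * rng.uniform(0.9, 1.1))
        row = {
            "name": name,
            "kind": "source" if name.endswith("contents") else "both",
            "mass_kg": round(mass, 6),
        }
        if name.endswith("wall"):
            row["wall_of"] = name.replace(" wall", " contents")
        if name in _BLOOD_FRACTIONS:
            row["blood_fraction"] = _BLOOD_FRACTIONS[name]
        rows.append(row)
    for name, mass in _SEX_REGIONS[sex]:
        rows.append({
            "name": name,
            "kind": "both",
            "mass_kg": round(float(mass * rng.uniform(0.9, 1.1)), 6),
        })
    return rows


def make_toy_phantom(spec: FixtureSpec) -> tuple[dict, dict]:
    """Male and female phantom-JSON dictionaries sharing non-sex regions."""
    rng = _rng(spec, 2)
    out = []
    for sex in ("male", "female"):
        rows = _region_rows(spec, sex, rng)
        total = round(sum(r["mass_kg"] for r in rows) * 1.08, 6)
        phantom = {
            "sex": sex,
            "total_body_mass_kg": total,
            "regions": rows,
            "substitutions": (
                {"aorta": "heart contents"}
                if any(r["name"] == "heart contents" for r in rows) else {}
            ),
        }
        out.append(phantom)
    return out[0], out[1]


def write_phantom(path: str | Path, phantom_dict: dict) -> None:
    Path(path).write_text(
        json.dumps(phantom_dict, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )


# --------------------------------------------------------------------- SAF

def make_toy_saf(spec: FixtureSpec, phantom_dict: dict) -> list[tuple]:
    """Rows (target, source, rtype, energy_MeV, saf_per_kg) for one phantom.

    Per source and radiation type, target shares are drawn once and
    scaled by a smooth, decreasing energy budget b(E) ≤ phi_budget, so
    Σ_T φ(T←S, E) = b(E) ≤ 1 holds at every grid energy.  Electron
    shares are tilted toward self-absorption in the source region.
    The total-body source rows are the mass-weighted combination of all
    per-source rows.
    """
    sex = phantom_dict["sex"]
    rng = _rng(spec, 3 if sex == "male" else 4)
    regions = phantom_dict["regions"]
    masses = {r["name"]: r["mass_kg"] for r in regions}
    targets = [r["name"] for r in regions if r["kind"] in ("target", "both")]
    sources = [r["name"] for r in regions]
    grid = np.asarray(spec.energy_grid, dtype=float)
    budget = spec.phi_budget * (0.55 + 0.45 * np.exp(-grid / 0.5))

    rows: list[tuple] = []
    total_mass = sum(masses[s] for s in sources)
    tb_phi = {rtype: np.zeros((len(targets), len(grid))) for rtype in ("photon", "electron")}
    for source in sources:
        for rtype in ("photon", "electron"):
            alpha = np.ones(len(targets))
            if rtype == "electron" and source in targets:
                alpha[targets.index(source)] = 25.0  # self-absorption dominates
            shares = rng.dirichlet(alpha)
            phi = np.outer(shares, budget)  # (targets, energies)
            tb_phi[rtype] += (masses[source] / total_mass) * phi
            for ti, target in enumerate(targets):
                for ei, energy in enumerate(grid):
                    rows.append((target, source, rtype, float(energy),
                                 float(phi[ti, ei] / masses[target])))
    for rtype in ("photon", "electron"):
        for ti, target in enumerate(targets):
            for ei, energy in enumerate(grid):
                rows.append((target, "total body", rtype, float(energy),
                             float(tb_phi[rtype][ti, ei] / masses[target])))
    return rows


def write_saf(path: str | Path, rows: list[tuple]) -> None:
    lines = ["target,source,radiation_type,energy_MeV,saf_per_kg"]
    for target, source, rtype, energy, saf in rows:
        lines.append(f"{target},{source},{rtype},{_fmt(energy)},{_fmt(saf)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# -------------------------------------------------------------- biokinetics

def make_toy_biokinetics(spec: FixtureSpec, nuclide: Nuclide) -> dict[str, dict]:
    """One closed-form-integrable model per biokinetic archetype.

    Archetypes mirror the adjustment rules: bladder-excreted,
    GI-excreted, bone-seeking (short and long effective half-time),
    blood-pool, total-body-with-organs residual, legacy-gut, and a
    plain multi-organ model used for oracle comparisons.
    """
    rng = _rng(spec, 5)
    lam = nuclide.decay_constant_per_h
    tb_total = 1.0 / lam

    def plain_entries():
        organs = ["liver", "kidneys", "spleen", "stomach wall"]
        coeffs = rng.dirichlet(np.ones(len(organs))) * 0.8
        return {
            organ: {"form": "exponential_sum",
                    "terms": [[float(c), lam * float(rng.uniform(1.0, 8.0))]]}
            for organ, c in zip(organs, coeffs)
        }

    models = {
        "plain": {"entries": plain_entries()},
        "bladder": {
            "entries": {
                "kidneys": {"form": "exponential_sum", "terms": [[0.25, lam + 2.0]]},
            },
            "urine_input": {
                "form": "exponential_sum",
                "terms": [[1.0, lam], [-1.0, lam + 1.0]],
            },
        },
        "gi": {
            "entries": {
                "liver": {"form": "exponential_sum", "terms": [[0.1, lam + 0.1]]},
            },
            "gi_input": {"amount": 0.9},
        },
        "bone_short": {
            "entries": {},
            "bone_entry": {"tia_h": 0.5 * tb_total, "t_eff_days": 2.0},
        },
        "bone_long": {
            "entries": {},
            "bone_entry": {"tia_h": 0.5 * tb_total, "t_eff_days": 20.0},
        },
        "blood": {"entries": {}, "blood_tia_h": 0.6 * tb_total},
        "legacy_gut": {
            "entries": {
                "upper large intestine": {"form": "tabulated_tia", "hours": 0.2 * tb_total},
                "lower large intestine": {"form": "tabulated_tia", "hours": 0.1 * tb_total},
            },
        },
        "residual": {
            "entries": {
                "total body": {"form": "exponential_sum", "terms": [[1.0, lam]]},
                "liver": {"form": "exponential_sum", "terms": [[0.2, lam + 0.05]]},
                "spleen": {"form": "exponential_sum", "terms": [[0.05, lam + 0.2]]},
            },
        },
    }
    for model in models.values():
        model["nuclide"] = nuclide.name
        model["half_life_h"] = nuclide.half_life_h
    return models


def write_model(path: str | Path, model_dict: dict) -> None:
    Path(path).write_text(
        json.dumps(model_dict, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )


# ------------------------------------------------------------------ corpus

def generate_corpus(seed: int, out_dir: str | Path,
                    spec: FixtureSpec | None = None) -> dict[str, Path]:
    """Write a complete runnable corpus: decay data, phantoms, SAFs,
    biokinetic models and a batch configuration.  Returns the paths."""
    spec = spec or FixtureSpec(seed=seed)
    if spec.seed != seed:
        spec = FixtureSpec(**{**spec.__dict__, "seed": seed})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    nuclide = make_toy_nuclide(spec)
    paths["decay"] = out / "decay.csv"
    write_decay_file(paths["decay"], [nuclide])

    male, female = make_toy_phantom(spec)
    for sex, phantom in (("male", male), ("female", female)):
        paths[f"phantom_{sex}"] = out / f"phantom_{sex}.json"
        write_phantom(paths[f"phantom_{sex}"], phantom)
        paths[f"saf_{sex}"] = out / f"saf_{sex}.csv"
        write_saf(paths[f"saf_{sex}"], make_toy_saf(spec, phantom))

    models = make_toy_biokinetics(spec, nuclide)
    for name, model in models.items():
        paths[f"model_{name}"] = out / f"model_{name}.json"
        write_model(paths[f"model_{name}"], model)

    batch = {
        "decay_file": "decay.csv",
        "phantoms": {"male": "phantom_male.json", "female": "phantom_female.json"},
        "saf": {"male": "saf_male.csv", "female": "saf_female.csv"},
        "voiding_interval_h": 3.5,
        "entries": [
            {"label": f"{nuclide.name} {archetype} agent",
             "nuclide": nuclide.name,
             "model": f"model_{archetype}.json",
             "old_e_mSv_per_MBq": old}
            for archetype, old in (
                ("plain", 1.0e-2), ("bladder", 5.0e-3), ("residual", 2.0e-2),
                ("blood", 8.0e-3), ("legacy_gut", 6.0e-3),
            )
        ],
    }
    paths["batch"] = out / "batch.yaml"
    import yaml as _yaml
    paths["batch"].write_text(_yaml.safe_dump(batch, sort_keys=True), encoding="utf-8")
    return paths


# ------------------------------------------------------------------ oracle

def _oracle_interp(energies, values, energy):
    """Independent SAF interpolation (log–log, clamped ends)."""
    if energy <= energies[0]:
        return values[0]
    if energy >= energies[-1]:
        return values[-1]
    for i in range(1, len(energies)):
        if energy <= energies[i]:
            e0, e1, v0, v1 = energies[i - 1], energies[i], values[i - 1], values[i]
            if energy == e1:
                return v1
            if v0 > 0 and v1 > 0:
                frac = (math.log(energy / e0)) / math.log(e1 / e0)
                return v0 * (v1 / v0) ** frac
            return v0 + (energy - e0) * (v1 - v0) / (e1 - e0)
    raise AssertionError("unreachable")


def oracle_dose(decay_path, saf_path, phantom_path, model_path,
                t_d: float = math.inf) -> dict[str, float]:
    """Naive nested-loop dose computation sharing no code with the engine.

    Supports models holding plain per-region entries (exponential sums
    or tabulated TIAs); the special-rule fields are out of its scope.
    Returns mGy/MBq per target region.
    """
    # decay file, parsed by hand
    lines = Path(decay_path).read_text(encoding="utf-8").splitlines()
    unit = lines[0].split("=")[1].strip()
    scale = 1.0 if unit == "MeV" else 1e-3
    emissions: dict[str, list[tuple[str, float, float]]] = {}
    for row in csv.DictReader(lines[1:]):
        emissions.setdefault(row["nuclide"], []).append(
            (row["radiation_type"], float(row["energy"]) * scale, float(row["yield"]))
        )

    model = json.loads(Path(model_path).read_text(encoding="utf-8"))
    for special in ("urine_input", "gi_input", "bone_entry", "blood_tia_h"):
        if model.get(special) is not None:
            raise ValueError(f"oracle_dose does not handle {special!r} models")
    nuclide = model["nuclide"]

    tia: dict[str, float] = {}
    for region, f in model["entries"].items():
        region = region.strip().lower()
        if f["form"] == "tabulated_tia":
            tia[region] = float(f["hours"])
        else:
            acc = 0.0
            for c, rate in f["terms"]:
                if t_d == math.inf:
                    acc += c / rate
                else:
                    acc += c * (1.0 - math.exp(-rate * t_d)) / rate
            tia[region] = acc

    # SAF rows, grouped by hand
    saf: dict[tuple, list[tuple[float, float]]] = {}
    with open(saf_path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            key = (row["target"].strip().lower(), row["source"].strip().lower(),
                   row["radiation_type"].strip())
            saf.setdefault(key, []).append(
                (float(row["energy_MeV"]), float(row["saf_per_kg"]))
            )
    for grid in saf.values():
        grid.sort()

    targets = sorted({t for t, _, _ in saf})
    doses = {}
    for target in targets:
        dose_gy = 0.0
        for source, hours in tia.items():
            s_val = 0.0
            for rtype, energy, yld in emissions[nuclide]:
                grid = saf[(target, source, rtype)]
                energies = [e for e, _ in grid]
                values = [v for _, v in grid]
                phi = _oracle_interp(energies, values, energy)
                s_val += energy * yld * 1.602176634e-13 * phi
            dose_gy += hours * s_val
        doses[target] = dose_gy * 3600.0 * 1e6 * 1e3
    return doses
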