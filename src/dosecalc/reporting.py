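"""Batch runner and comparison reporting.

Runs the full chain (decay data → S values → TIA → absorbed dose →
effective dose under both weighting schemes) for every entry of a batch
configuration, compares the new E/A₀ coefficients against previously
published reference values, and emits the comparison table, summary
statistics, and the binned distribution of percentage differences.

Percentage differences are printed as integers rounded half away from
zero (so −7.5% prints as −8).  E/A₀ values export in scientific
E-notation with three significant figures.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import yaml

from .biokinetics import DEFAULT_VOIDING_INTERVAL_H, load_model, resolve_model
from .catalog import OTHER_TISSUES, TOTAL_BODY
from .dose import absorbed_dose
from .effective import (
    effective_dose_icrp60,
    effective_dose_icrp103,
    load_weighting_scheme,
)
from .errors import DosecalcError, FormatError
from .nucleardata import parse_decay_file
from .phantom import load_phantom, load_saf
from .svalue import build_svalue_matrix

logger = logging.getLogger(__name__)

DEFAULT_BIN_EDGES = tuple(range(-100, 101, 10))


def format_e(value: float) -> str:
    """Three-significant-figure scientific notation, e.g. 1.59E-02."""
    return f"{value:.2E}"


def percent_difference(new: float, old: float) -> int:
    """Integer percent difference 100·(new−old)/old, ties rounded away from zero.

    Computed in decimal arithmetic so that printed coefficients landing
    exactly on a .5 boundary round deterministically (−7.5 → −8).
    """
    if old <= 0:
        raise ValueError(f"reference value must be > 0, got {old}")
    d_new, d_old = Decimal(str(new)), Decimal(str(old))
    x = (d_new - d_old) / d_old * 100
    return int(x.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass
class ComparisonRow:
    """One radiopharmaceutical's old-vs-new effective-dose comparison."""

    label: str
    e_old: float | None = None
    e_new_icrp60: float | None = None
    e_new_icrp103: float | None = None
    e_male: float | None = None
    e_female: float | None = None
    pct_icrp60: int | None = None
    pct_icrp103: int | None = None
    failed: bool = False
    error: str = ""


@dataclass
class SummaryStats:
    """Distribution summary of the integer percent differences."""

    n: int
    fraction_lower: float
    mean_percent: float
    n_beyond_100: int
    bin_edges: tuple
    counts: tuple  # underflow, per-bin..., overflow


def summarize(rows: list[ComparisonRow], bin_edges=DEFAULT_BIN_EDGES,
              which: str = "pct_icrp103") -> SummaryStats:
    """Summary statistics over the percent differences of successful rows."""
    diffs = [getattr(r, which) for r in rows if not r.failed and getattr(r, which) is not None]
    if not diffs:
        raise ValueError("no successful comparison rows to summarize")
    diffs = np.asarray(diffs, dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    inner, _ = np.histogram(diffs, bins=edges)
    underflow = int(np.sum(diffs < edges[0]))
    overflow = int(np.sum(diffs >= edges[-1]))
    # np.histogram closes the right edge of the last bin; shift such hits
    # into the overflow bucket so counts partition the rows
    on_last_edge = int(np.sum(diffs == edges[-1]))
    if on_last_edge:
        inner = inner.copy()
        inner[-1] -= on_last_edge
    return SummaryStats(
        n=len(diffs),
        fraction_lower=float(np.mean(diffs < 0)),
        mean_percent=float(np.mean(diffs)),
        n_beyond_100=int(np.sum(np.abs(diffs) > 100)),
        bin_edges=tuple(edges.tolist()),
        counts=(underflow, *inner.tolist(), overflow),
    )


@dataclass
class CollectiveDoseResult:
    new_total_man_sv: float
    percent_reduction: int


def rescale_collective_dose(
    old_total_man_sv: float,
    ratio: float | None = None,
    per_exam: list[tuple[float, float]] | None = None,
    new_total_man_sv: float | None = None,
) -> CollectiveDoseResult:
    """Rescale a collective effective dose by new-to-old E/A₀ ratios.

    Accepts an aggregate ratio, a per-exam-category list of
    (old manSv, ratio) pairs, or a directly known new total.  The
    percent reduction is rounded half away from zero.
    """
    if old_total_man_sv <= 0:
        raise ValueError("old collective dose must be > 0")
    given = [x is not None for x in (ratio, per_exam, new_total_man_sv)]
    if sum(given) != 1:
        raise ValueError("provide exactly one of ratio, per_exam, new_total_man_sv")
    if ratio is not None:
        if ratio <= 0:
            raise ValueError("ratio must be > 0")
        new_total = old_total_man_sv * ratio
    elif per_exam is not None:
        if not per_exam:
            raise ValueError("per_exam table is empty")
        new_total = sum(old_i * r_i for old_i, r_i in per_exam)
        if new_total <= 0:
            raise ValueError("per_exam table yields nonpositive total")
    else:
        new_total = float(new_total_man_sv)
        if new_total <= 0:
            raise ValueError("new collective dose must be > 0")
    reduction = -percent_difference(new_total, old_total_man_sv)
    return CollectiveDoseResult(new_total_man_sv=new_total, percent_reduction=reduction)


@dataclass
class BatchResult:
    rows: list[ComparisonRow]
    summary: SummaryStats | None
    failures: list[str] = field(default_factory=list)


def _compute_entry(entry, shared, schemes):
    """Run the full dose chain for one batch entry; returns a ComparisonRow."""
    label = entry["label"]
    nuclide_name = entry["nuclide"]
    nuclide = shared["nuclides"][nuclide_name]
    results = {}
    doses = {}
    for sex in ("male", "female"):
        phantom = shared["phantoms"][sex]
        saf = shared["saf"][sex]
        model_path = entry["model"][sex] if isinstance(entry["model"], dict) else entry["model"]
        model = load_model(Path(shared["base"]) / model_path)
        tia = resolve_model(
            model,
            phantom,
            voiding_interval_h=shared["voiding_interval_h"],
            physical_half_life_h=nuclide.half_life_h,
        )
        logger.info("%s [%s]: rules applied: %s", label, sex,
                    "; ".join(tia.provenance))
        sources = sorted(tia.entries)
        if OTHER_TISSUES in tia.entries:
            sources = sorted(set(sources) - {OTHER_TISSUES} | {TOTAL_BODY})
        targets = saf.targets()
        matrix = build_svalue_matrix(nuclide, phantom, saf, sources, targets)
        doses[sex] = absorbed_dose(tia, matrix, phantom, targets)
    phantoms = shared["phantoms"]
    if "ICRP60" in schemes:
        results["ICRP60"] = effective_dose_icrp60(
            doses["male"], doses["female"],
            phantom_male=phantoms["male"], phantom_female=phantoms["female"],
        )
    if "ICRP103" in schemes:
        results["ICRP103"] = effective_dose_icrp103(
            doses["male"], doses["female"],
            phantom_male=phantoms["male"], phantom_female=phantoms["female"],
        )
    old = entry.get("old_e_mSv_per_MBq")
    r60 = results.get("ICRP60")
    r103 = results.get("ICRP103")
    return ComparisonRow(
        label=label,
        e_old=old,
        e_new_icrp60=r60.e_ref if r60 else None,
        e_new_icrp103=r103.e_ref if r103 else None,
        e_male=r103.e_male if r103 else None,
        e_female=r103.e_female if r103 else None,
        pct_icrp60=percent_difference(r60.e_ref, old) if (r60 and old) else None,
        pct_icrp103=percent_difference(r103.e_ref, old) if (r103 and old) else None,
    )


def run_batch(
    config_path: str | Path,
    out_dir: str | Path | None = None,
    schemes: tuple[str, ...] = ("ICRP60", "ICRP103"),
) -> BatchResult:
    """Run every entry of a batch configuration and build the comparison.

    Per-entry failures are collected and reported at the end without
    aborting the batch.  Rows are ordered deterministically by label.
    """
    config_path = Path(config_path)
    config = yaml.safe_load(config_path.read_text(encoding="utf-8"))
    base = config_path.parent
    for scheme in schemes:
        load_weighting_scheme(scheme)  # validate early
    try:
        shared = {
            "base": base,
            "nuclides": {
                n.name: n for n in parse_decay_file(base / config["decay_file"])
            },
            "phantoms": {
                sex: load_phantom(base / path)
                for sex, path in config["phantoms"].items()
            },
            "saf": {
                sex: load_saf(base / path) for sex, path in config["saf"].items()
            },
            "voiding_interval_h": float(
                config.get("voiding_interval_h", DEFAULT_VOIDING_INTERVAL_H)
            ),
        }
    except KeyError as exc:
        raise FormatError(f"{config_path}: missing batch field {exc}") from None

    rows: list[ComparisonRow] = []
    failures: list[str] = []
    for entry in sorted(config["entries"], key=lambda e: e["label"]):
        try:
            rows.append(_compute_entry(entry, shared, schemes))
        except (DosecalcError, KeyError, ValueError) as exc:
            failures.append(f"{entry.get('label', '?')}: {exc}")
            rows.append(ComparisonRow(label=entry.get("label", "?"), failed=True,
                                      error=str(exc)))
    ok = [r for r in rows if not r.failed and r.pct_icrp103 is not None]
    summary = summarize(rows) if ok else None
    if failures:
        logger.error("batch completed with %d failed entries: %s",
                     len(failures), "; ".join(failures))
    if out_dir is not None:
        _write_outputs(rows, summary, Path(out_dir))
    return BatchResult(rows=rows, summary=summary, failures=failures)


def _write_outputs(rows, summary, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = ["label,e_old,e_new_icrp60,pct_icrp60,e_new_icrp103,pct_icrp103,"
             "e_male_icrp103,e_female_icrp103,failed"]
    for r in rows:
        def fmt(x):
            return format_e(x) if isinstance(x, float) else ("" if x is None else str(x))
        lines.append(",".join([
            f'"{r.label}"', fmt(r.e_old), fmt(r.e_new_icrp60), fmt(r.pct_icrp60),
            fmt(r.e_new_icrp103), fmt(r.pct_icrp103), fmt(r.e_male),
            fmt(r.e_female), str(int(r.failed)),
        ]))
    (out_dir / "comparison.csv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    if summary is not None:
        (out_dir / "summary.json").write_text(
            json.dumps(
                {
                    "n": summary.n,
                    "fraction_lower": summary.fraction_lower,
                    "mean_percent": summary.mean_percent,
                    "n_beyond_100": summary.n_beyond_100,
                },
                indent=2,
            ) + "\n",
            encoding="utf-8",
        )
        hist = ["bin_low,bin_high,count"]
        edges = summary.bin_edges
        hist.append(f"-inf,{edges[0]},{summary.counts[0]}")
        for i in range(len(edges) - 1):
            hist.append(f"{edges[i]},{edges[i + 1]},{summary.counts[i + 1]}")
        hist.append(f"{edges[-1]},inf,{summary.counts[-1]}")
        (out_dir / "histogram.csv").write_text("\n".join(hist) + "\n", encoding="utf-8")


def plot_histogram(summary: SummaryStats, path: str | Path) -> None:
    """Render the percent-difference distribution as a bar chart."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    edges = summary.bin_edges
    centers = [0.5 * (edges[i] + edges[i + 1]) for i in range(len(edges) - 1)]
    width = edges[1] - edges[0]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(centers, summary.counts[1:-1], width=width * 0.9, color="0.2")
    ax.set_xlabel("difference between new and old E/A$_0$ (%)")
    ax.set_ylabel("number of radiopharmaceuticals")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
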