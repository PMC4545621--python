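"""Absorbed-dose coefficients: D(r_T) = Σ_S Ã(r_S) · S(r_T ← r_S).

Internal computation is SI (hours × Gy/decay); the published convention
mGy per MBq administered is applied exactly once at the boundary:
1 h of TIA per MBq is 3600 s × 10⁶ decays/s = 3.6×10⁹ transformations,
and Gy → mGy contributes a further 10³.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .catalog import OTHER_TISSUES, TOTAL_BODY, normalize_region
from .errors import MissingGeometryError
from .phantom import Phantom
from .svalue import SValueMatrix, other_tissue_svalue

logger = logging.getLogger(__name__)

#: transformations per (MBq administered × hour of TIA)
DECAYS_PER_MBQ_HOUR = 3.6e9
GY_TO_MGY = 1e3
#: net factor from (TIA hours × Gy/decay) to mGy/MBq
MGY_PER_MBQ = DECAYS_PER_MBQ_HOUR * GY_TO_MGY

_COLON_SEGMENT_WALLS = ("right colon wall", "left colon wall", "rectosigmoid colon wall")


@dataclass
class DoseCoefficientResult:
    """Absorbed dose per unit administered activity, mGy/MBq, per target."""

    sex: str
    doses: dict[str, float] = field(default_factory=dict)
    nuclide: str = ""
    phantom_id: str = ""
    model_id: str = ""

    def get(self, target: str) -> float:
        return self.doses[normalize_region(target)]

    def __contains__(self, target: str) -> bool:
        return normalize_region(target, strict=False) in self.doses


def absorbed_dose(
    tia,
    matrix: SValueMatrix,
    phantom: Phantom,
    targets: list[str],
) -> DoseCoefficientResult:
    """Fold a TIA vector with an S-value matrix into dose coefficients.

    The "other organs and tissues" source is routed through the exact
    remainder S value with the accounted-source list equal to the
    model's explicit TIA sources.  ``tia`` may be a TIAVector or a plain
    region → hours mapping.
    """
    entries = dict(getattr(tia, "entries", tia))
    explicit = [s for s in entries if normalize_region(s) not in (OTHER_TISSUES, TOTAL_BODY)]
    doses: dict[str, float] = {}
    for target in targets:
        target = normalize_region(target)
        d = 0.0
        for source, hours in entries.items():
            source = normalize_region(source)
            if source == OTHER_TISSUES:
                s_val = other_tissue_svalue(matrix, phantom, target, explicit)
            else:
                try:
                    s_val = matrix.get(target, source)
                except MissingGeometryError:
                    raise MissingGeometryError(target, source) from None
            d += hours * s_val
        doses[target] = d * MGY_PER_MBQ
    return DoseCoefficientResult(
        sex=phantom.sex,
        doses=doses,
        nuclide=matrix.nuclide,
        phantom_id=matrix.phantom_id,
    )


def colon_target_dose(doses: DoseCoefficientResult | dict, phantom: Phantom) -> float:
    """Composite colon dose: mass-weighted mean of the segment wall doses.

    The weighting uses the wall masses (the dose targets are walls).  A
    zero-mass segment is excluded with a warning.
    """
    table = dict(getattr(doses, "doses", doses))
    weighted = 0.0
    mass_sum = 0.0
    for segment in _COLON_SEGMENT_WALLS:
        key = normalize_region(segment)
        if key not in table:
            raise KeyError(f"colon segment dose missing: {segment!r}")
        try:
            mass = phantom.mass(segment)
        except KeyError:
            mass = 0.0
        if mass <= 0.0:
            logger.warning("colon segment %r has no mass; excluded from weighting", segment)
            continue
        weighted += mass * table[key]
        mass_sum += mass
    if mass_sum == 0.0:
        raise ValueError("no colon segment carries mass; composite dose undefined")
    return weighted / mass_sum


def export_dose_csv(result: DoseCoefficientResult, path: str | Path) -> None:
    """Write the dose table as CSV: sex,target,dose_mGy_per_MBq."""
    lines = ["sex,target,dose_mGy_per_MBq"]
    for target, value in sorted(result.doses.items()):
        lines.append(f"{result.sex},{target},{value:.6e}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
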