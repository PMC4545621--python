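"""S-value assembly: mean absorbed dose to a target per transformation in a source.

S(r_T ← r_S) = Σᵢ Δᵢ · Φ(r_T ← r_S, Eᵢ) with Δᵢ = Eᵢ·Yᵢ converted to
joules, giving Gy per nuclear transformation when Φ is in kg⁻¹.
Electrons and photons both use their own SAF entries; no local-absorption
shortcut is taken for charged particles.

The "other organs and tissues" source is handled by the exact
remainder solution: the total-body S value with the already-accounted
source contributions removed, re-normalized to the remaining mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .catalog import TOTAL_BODY, normalize_region
from .errors import DegenerateRemainderError, MissingGeometryError
from .nucleardata import Nuclide
from .phantom import Phantom, SAFPolicy, SAFTable, saf_lookup

logger = logging.getLogger(__name__)

#: 1 MeV in joules (CODATA exact).
MEV_TO_J = 1.602176634e-13


@dataclass
class SValueMatrix:
    """Dense S-value lookup over requested (target, source) pairs, Gy/decay."""

    sex: str
    values: dict[tuple[str, str], float]
    nuclide: str = ""
    phantom_id: str = ""
    #: source regions whose SAF rows came from a substitute region
    substituted: dict[str, str] = field(default_factory=dict)

    def get(self, target: str, source: str) -> float:
        key = (normalize_region(target), normalize_region(source))
        try:
            return self.values[key]
        except KeyError:
            raise MissingGeometryError(*key) from None

    def __contains__(self, key) -> bool:
        return (normalize_region(key[0]), normalize_region(key[1])) in self.values


def compute_svalue(
    nuclide: Nuclide,
    saf: SAFTable,
    target: str,
    source: str,
    policy: SAFPolicy = SAFPolicy(),
) -> float:
    """S(target ← source) in Gy per nuclear transformation."""
    total = 0.0
    for emission in nuclide.emissions:
        if emission.yield_per_decay == 0.0:
            continue
        phi = saf_lookup(saf, target, source, emission.radiation_type,
                         emission.energy_mev, policy=policy)
        total += emission.delta_mev * MEV_TO_J * phi
    return total


def build_svalue_matrix(
    nuclide: Nuclide,
    phantom: Phantom,
    saf: SAFTable,
    sources: list[str],
    targets: list[str],
    policy: SAFPolicy = SAFPolicy(),
) -> SValueMatrix:
    """Assemble the dense S-value matrix over the requested pairs.

    A source without SAF rows falls back to the phantom's substitution
    map (e.g. aorta → heart contents); substitutions used are recorded.
    """
    values: dict[tuple[str, str], float] = {}
    substituted: dict[str, str] = {}
    rtypes = {e.radiation_type for e in nuclide.emissions if e.yield_per_decay > 0}
    for source in sources:
        source = normalize_region(source)
        actual = source
        has_rows = any((normalize_region(t), source, r) in saf.entries
                       for t in targets for r in rtypes)
        if not has_rows:
            resolved, was_sub = phantom.resolve_source(source)
            if was_sub:
                actual = resolved
                substituted[source] = resolved
                logger.info("source %r substituted by %r", source, resolved)
        for target in targets:
            target = normalize_region(target)
            values[(target, source)] = compute_svalue(
                nuclide, saf, target, actual, policy=policy
            )
    return SValueMatrix(
        sex=phantom.sex,
        values=values,
        nuclide=nuclide.name,
        phantom_id=f"{phantom.sex}:{phantom.total_body_mass_kg:g}kg",
        substituted=substituted,
    )


def other_tissue_svalue(
    matrix: SValueMatrix,
    phantom: Phantom,
    target: str,
    accounted_sources: list[str],
) -> float:
    """S(target ← other organs and tissues) by the exact remainder formula.

    (m_TB·S(T←TB) − Σ_s m_s·S(T←s)) / (m_TB − Σ_s m_s) over the source
    regions already accounted for explicitly.  A negative result (only
    possible with physically inconsistent inputs) is clamped to zero
    with a warning.
    """
    target = normalize_region(target)
    s_tb = matrix.get(target, TOTAL_BODY)
    m_tb = phantom.total_body_mass_kg
    mass_sum = 0.0
    weighted = 0.0
    for source in accounted_sources:
        source = normalize_region(source)
        m_s = phantom.mass(source)
        mass_sum += m_s
        weighted += m_s * matrix.get(target, source)
    if mass_sum >= m_tb:
        raise DegenerateRemainderError(
            f"accounted source masses ({mass_sum:g} kg) >= total body mass ({m_tb:g} kg)"
        )
    result = (m_tb * s_tb - weighted) / (m_tb - mass_sum)
    if result < 0.0:
        logger.warning(
            "negative remainder S value %.3e for target %r clamped to 0 "
            "(inconsistent inputs)", result, target,
        )
        return 0.0
    return result


def export_svalue_csv(matrix: SValueMatrix, path: str | Path) -> None:
    """Write the matrix as CSV: target,source,s_gy_per_decay,substituted."""
    lines = ["target,source,s_gy_per_decay,substituted"]
    for (target, source), value in sorted(matrix.values.items()):
        sub = matrix.substituted.get(source, "")
        lines.append(f"{target},{source},{value:.12e},{sub}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
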