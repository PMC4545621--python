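"""Canonical region catalogue and name normalization.

The catalogue follows the ICRP/ICRU reference-phantom naming with the
alimentary tract segmented per the Human Alimentary Tract Model (oral
cavity, oesophagus, stomach, small intestine, right colon, left colon,
rectosigmoid colon).  The legacy gut regions of the older stylized
phantom (upper/lower large intestine) are kept only as inputs to the
colon-conversion rule, never as output regions.

Walled organs follow the ``<organ> wall`` / ``<organ> contents``
convention: activity resides in the contents, the radiosensitive target
is the wall.
"""

from __future__ import annotations

import difflib
import re

from .errors import UnknownRegionError

TOTAL_BODY = "total body"
OTHER_TISSUES = "other organs and tissues"
LEGACY_ULI = "upper large intestine"
LEGACY_LLI = "lower large intestine"

#: HATM segmentation of the alimentary tract.
ALIMENTARY_SEGMENTS = (
    "oral cavity",
    "oesophagus",
    "stomach",
    "small intestine",
    "right colon",
    "left colon",
    "rectosigmoid colon",
)

#: Organs represented as wall/contents pairs.
WALLED_ORGANS = (
    "stomach",
    "small intestine",
    "right colon",
    "left colon",
    "rectosigmoid colon",
    "urinary bladder",
    "gall bladder",
    "heart",
)

#: Skeletal compartments used by the bone-partition rule.
BONE_COMPARTMENTS = (
    "trabecular bone surface",
    "cortical bone surface",
    "trabecular bone volume",
    "cortical bone volume",
)

_SOLID_REGIONS = (
    "adrenals",
    "aorta",
    "blood",
    "bone surface",
    "brain",
    "breast",
    "colon",  # composite target used by the tissue-weighting schemes
    "extrathoracic region",
    "kidneys",
    "liver",
    "lungs",
    "lymphatic nodes",
    "muscle",
    "oesophagus",
    "oral cavity",
    "oral mucosa",
    "ovaries",
    "pancreas",
    "prostate",
    "red marrow",
    "salivary glands",
    "skin",
    "spleen",
    "testes",
    "thymus",
    "thyroid",
    "uterus",
    "gonads",
)

CANONICAL_REGIONS = frozenset(
    list(_SOLID_REGIONS)
    + [f"{organ} wall" for organ in WALLED_ORGANS]
    + [f"{organ} contents" for organ in WALLED_ORGANS]
    + list(BONE_COMPARTMENTS)
    + [TOTAL_BODY, OTHER_TISSUES, LEGACY_ULI, LEGACY_LLI]
)

ALIASES = {
    "lung": "lungs",
    "red bone marrow": "red marrow",
    "active marrow": "red marrow",
    "esophagus": "oesophagus",
    "kidney": "kidneys",
    "uli": LEGACY_ULI,
    "lli": LEGACY_LLI,
    "uli wall": LEGACY_ULI,
    "lli wall": LEGACY_LLI,
    "upper large intestine wall": LEGACY_ULI,
    "lower large intestine wall": LEGACY_LLI,
    "urinary bladder content": "urinary bladder contents",
    "bladder wall": "urinary bladder wall",
    "bladder contents": "urinary bladder contents",
    "heart content": "heart contents",
    "gallbladder wall": "gall bladder wall",
    "gallbladder contents": "gall bladder contents",
    "whole body": TOTAL_BODY,
    "remainder": OTHER_TISSUES,
    "other organs and tissue": OTHER_TISSUES,
    "adrenal glands": "adrenals",
    "et region": "extrathoracic region",
    "lymph nodes": "lymphatic nodes",
}

_WS = re.compile(r"[\s_\-]+")


def _key(name: str) -> str:
    return _WS.sub(" ", str(name).strip().lower())


def normalize_region(name: str, strict: bool = True) -> str:
    """Resolve *name* to its canonical catalogue entry.

    Matching is case-, whitespace- and separator-insensitive; known
    aliases (e.g. ``red bone marrow``) are mapped onto canonical names.
    With ``strict=True`` an unresolvable name raises
    :class:`~dosecalc.errors.UnknownRegionError` listing the nearest
    catalogue candidates.
    """
    key = _key(name)
    if key in ALIASES:
        key = ALIASES[key]
    if key in CANONICAL_REGIONS:
        return key
    if not strict:
        return key
    pool = sorted(CANONICAL_REGIONS | set(ALIASES))
    raise UnknownRegionError(name, difflib.get_close_matches(key, pool, n=3))


def is_legacy(name: str) -> bool:
    """True for the old stylized-phantom gut regions (conversion inputs only)."""
    return normalize_region(name) in (LEGACY_ULI, LEGACY_LLI)
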