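"""Amino-acid physico-chemical codes and their semantic categories.

Each of the 20 standard amino acids carries four small integer codes —
volume, hydrophobicity, charge, polarity — obtained by binning literature
property scales.  Codes are mapped to ordinal semantic labels
(e.g. very_small … very_large) because the rule learner works on categorical
values.  Volume codes run 1–5 and are labelled by rank order; hydrophobicity
runs 0–3, charge −1..1, polarity 0–1.
"""

from __future__ import annotations

import logging
import math

from .datamodel import ValidationError

log = logging.getLogger(__name__)

PROPERTIES = ("volume", "hydrophobicity", "polarity", "charge")
MODES = ("average", "total")

# Per-residue codes: (volume, hydrophobicity, charge, polarity).
AA_PROPERTY_CODES: dict[str, tuple[int, int, int, int]] = {
    "A": (1, 2, 0, 1),
    "C": (2, 2, 0, 1),
    "D": (2, 0, -1, 0),
    "E": (3, 0, -1, 0),
    "F": (5, 3, 0, 1),
    "G": (1, 1, 0, 1),
    "H": (3, 1, 1, 0),
    "I": (4, 3, 0, 1),
    "K": (4, 0, 1, 0),
    "L": (4, 3, 0, 1),
    "M": (4, 3, 0, 1),
    "N": (2, 0, 0, 0),
    "P": (2, 0, 0, 1),
    "Q": (3, 1, 0, 0),
    "R": (4, 0, 1, 0),
    "S": (1, 1, 0, 0),
    "T": (2, 1, 0, 0),
    "V": (3, 3, 0, 1),
    "W": (5, 3, 0, 0),
    "Y": (5, 2, 0, 0),
}

_PROPERTY_INDEX = {"volume": 0, "hydrophobicity": 1, "charge": 2, "polarity": 3}

# Ordinal code -> semantic label, per property.
SEMANTIC_SCALES: dict[str, tuple[tuple[int, str], ...]] = {
    "volume": (
        (1, "very_small"),
        (2, "small"),
        (3, "medium"),
        (4, "large"),
        (5, "very_large"),
    ),
    "hydrophobicity": (
        (0, "hydrophilic"),
        (1, "neutral"),
        (2, "hydrophobic"),
        (3, "very_hydrophobic"),
    ),
    "polarity": ((0, "polar"), (1, "apolar")),
    "charge": ((-1, "negative"), (0, "neutral"), (1, "positive")),
}

SEMANTIC_LABELS = {
    prop: tuple(label for _, label in scale) for prop, scale in SEMANTIC_SCALES.items()
}


def aa_properties(residue: str) -> tuple[int, int, int, int]:
    """Return the (volume, hydrophobicity, charge, polarity) codes of one residue."""
    try:
        return AA_PROPERTY_CODES[residue]
    except KeyError:
        raise ValidationError(f"unknown amino acid {residue!r}") from None


def property_code(residue: str, prop: str) -> int:
    if prop not in _PROPERTY_INDEX:
        raise ValidationError(f"unknown property {prop!r}")
    return aa_properties(residue)[_PROPERTY_INDEX[prop]]


def indel_numeric(residues: str, prop: str, mode: str) -> float:
    """Total (sum) or average of a property's codes over a residue string."""
    if mode not in MODES:
        raise ValidationError(f"unknown mode {mode!r}")
    codes = [property_code(aa, prop) for aa in residues]
    total = float(sum(codes))
    return total if mode == "total" else total / len(codes)


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def to_semantic(value: float, prop: str, mode: str, n_residues: int = 1) -> str:
    """Map a numeric property value onto its semantic label.

    Averages are rounded (half away from zero) to the nearest code.  Totals
    are first divided by the indel length so they land on the same
    per-residue code scale, then mapped identically.  A value that rounds
    outside the scale is clamped to the nearest end with a warning.
    """
    if mode == "total":
        if n_residues < 1:
            raise ValidationError("n_residues must be >= 1 for totals")
        value = value / n_residues
    scale = SEMANTIC_SCALES[prop]
    code = round_half_away(value)
    codes = [c for c, _ in scale]
    if code < codes[0] or code > codes[-1]:
        clamped = min(max(code, codes[0]), codes[-1])
        log.warning(
            "%s code %d outside scale [%d, %d]; clamped to %d",
            prop,
            code,
            codes[0],
            codes[-1],
            clamped,
        )
        code = clamped
    return dict(scale)[code]


def indel_semantic(residues: str, prop: str, mode: str) -> str:
    """Semantic label of an indel's property value (average or total)."""
    value = indel_numeric(residues, prop, mode)
    return to_semantic(value, prop, mode, n_residues=len(residues))
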