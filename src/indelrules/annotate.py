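"""Compute the categorical feature vector of an NFS-Indel from its protein.

The feature set mixes evolutionary signals (conserved residues, conserved
core blocks), functional annotations (Pfam/Prosite/UniProt/alignment-derived
domains), the physico-chemical make-up of the indel itself, the local
perturbation it induces relative to three widening sequence scopes, and
structural context (disorder probability, solvent accessibility, secondary
structure), plus position and length descriptors.

Scopes of the local perturbation, for an indel of n residues:

* **site** — the residues that take the place of a deletion (the n residues
  immediately downstream of the deleted span, falling back to the upstream
  residues at the C-terminus) or the n reference residues at the position of
  an insertion;
* **environment** — the n residues flanking the indel on each side;
* **region** — the 2n residues flanking on each side.

Flanks are truncated at the protein ends.  The perturbation is the property
value of the scope minus that of the indel residues (average or total),
rounded half away from zero and clamped to the five ordinal categories
two_less … two_more.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .datamodel import (
    DELETION,
    INSERTION,
    INTERVAL_CLASSES,
    AnnotationError,
    FeatureSchema,
    IndelVariant,
    LabeledDataset,
    ProteinContext,
    Record,
)
from .properties import (
    MODES,
    PROPERTIES,
    SEMANTIC_LABELS,
    indel_numeric,
    indel_semantic,
    round_half_away,
)

SCOPES = ("site", "environment", "region")

PERTURBATION_LABELS = ("two_less", "one_less", "equal", "one_more", "two_more")
_PERTURBATION_BY_CODE = {
    -2: "two_less",
    -1: "one_less",
    0: "equal",
    1: "one_more",
    2: "two_more",
}

DISORDER_LABELS = ("structured", "semi_disorder", "disorder")
RSA_LABELS = ("fully_buried", "buried", "intermediate", "exposed", "fully_exposed")
SS_LABELS = ("coil", "helix", "strand", "two")
RIP_LABELS = ("n_terminal", "middle", "c_terminal")
LENGTH_LABELS = ("one", "more_than_one")
BOOL_LABELS = ("true", "false")


def _bool(flag: bool) -> str:
    return "true" if flag else "false"


def build_schema() -> FeatureSchema:
    """The full annotation schema, in presentation order."""
    params: list[tuple[str, tuple[str, ...]]] = [
        ("conserved_residue", BOOL_LABELS),
        ("block", BOOL_LABELS),
        ("pfam", BOOL_LABELS),
        ("prosite", BOOL_LABELS),
        ("uniprot_domain", BOOL_LABELS),
        ("macsims_domain", BOOL_LABELS),
    ]
    for mode in MODES:
        for prop in PROPERTIES:
            params.append((f"indel_{prop}_{mode}", SEMANTIC_LABELS[prop]))
    for mode in MODES:
        for scope in SCOPES:
            for prop in PROPERTIES:
                params.append(
                    (
                        f"local_perturbation_{scope}_{prop}_{mode}",
                        PERTURBATION_LABELS,
                    )
                )
    params += [
        ("probability_of_disorder", DISORDER_LABELS),
        ("rsa", RSA_LABELS),
        ("secondary_structure", SS_LABELS),
        ("relative_indel_position", RIP_LABELS),
        ("indel_length", LENGTH_LABELS),
        ("has_proline", BOOL_LABELS),
        ("has_glycine", BOOL_LABELS),
    ]
    return FeatureSchema(params)


ANNOTATION_SCHEMA = build_schema()


@dataclass(frozen=True)
class LocalSequences:
    """Site/environment/region residue strings plus the site's residue span."""

    site: str
    site_span: tuple[int, int]
    environment: str
    region: str

    def scope(self, name: str) -> str:
        if name not in SCOPES:
            raise AnnotationError(f"unknown scope {name!r}")
        return getattr(self, name)


def _slice(sequence: str, start: int, end: int) -> str:
    """Residues at 1-based closed positions [start, end], clipped to the protein."""
    start = max(start, 1)
    end = min(end, len(sequence))
    if start > end:
        return ""
    return sequence[start - 1 : end]


def local_sequences(variant: IndelVariant, context: ProteinContext) -> LocalSequences:
    variant.validate_against(context.sequence)
    seq = context.sequence
    n = variant.length
    pos = variant.position

    if variant.kind == DELETION:
        # flanks are taken around the deleted span [pos, pos + n - 1]
        left_end, right_start = pos - 1, pos + n
        site_start = pos + n
    else:
        # insertion point sits between residues pos - 1 and pos
        left_end, right_start = pos - 1, pos
        site_start = pos

    site = _slice(seq, site_start, site_start + n - 1)
    span = (max(site_start, 1), min(site_start + n - 1, len(seq)))
    if not site:
        # indel at the extreme C-terminus: fall back to the preceding residues
        site = _slice(seq, left_end - n + 1, left_end)
        span = (max(left_end - n + 1, 1), min(left_end, len(seq)))
        if not site:
            raise AnnotationError(
                f"{variant.protein_id}: no site residues on either side of the "
                f"indel at position {pos}"
            )

    environment = _slice(seq, left_end - n + 1, left_end) + _slice(
        seq, right_start, right_start + n - 1
    )
    region = _slice(seq, left_end - 2 * n + 1, left_end) + _slice(
        seq, right_start, right_start + 2 * n - 1
    )
    if not environment or not region:
        raise AnnotationError(
            f"{variant.protein_id}: indel at position {pos} has no flanking "
            f"residues to define its environment"
        )
    return LocalSequences(site, span, environment, region)


def perturbation_value(
    variant: IndelVariant,
    context: ProteinContext,
    scope: str,
    prop: str,
    mode: str,
) -> float:
    """Numeric perturbation d = value(scope residues) − value(indel residues)."""
    scope_residues = local_sequences(variant, context).scope(scope)
    return indel_numeric(scope_residues, prop, mode) - indel_numeric(
        variant.residues, prop, mode
    )


def perturbation_category(d: float) -> str:
    code = round_half_away(d)
    return _PERTURBATION_BY_CODE[min(max(code, -2), 2)]


def perturbation(
    variant: IndelVariant,
    context: ProteinContext,
    scope: str,
    prop: str,
    mode: str,
) -> str:
    return perturbation_category(perturbation_value(variant, context, scope, prop, mode))


def _site_mean(track, span: tuple[int, int]) -> float:
    start, end = span
    values = track[start - 1 : end]
    return sum(values) / len(values)


def disorder_category(variant: IndelVariant, context: ProteinContext) -> str:
    """Bin the mean disorder probability P over the site: structured
    (P < 0.4), semi_disorder (0.4 <= P <= 0.7), disorder (P > 0.7)."""
    p = _site_mean(context.disorder, local_sequences(variant, context).site_span)
    if p < 0.4:
        return "structured"
    if p > 0.7:
        return "disorder"
    return "semi_disorder"


def rsa_category(variant: IndelVariant, context: ProteinContext) -> str:
    """Bin the mean solvent-accessibility value R_v over the site into five
    left-closed bins of width 30: [0,30) fully_buried … [120,inf) fully_exposed."""
    rv = _site_mean(context.rsa, local_sequences(variant, context).site_span)
    if rv < 0:
        raise AnnotationError(f"{variant.protein_id}: negative RSA value {rv}")
    return RSA_LABELS[min(int(rv // 30), 4)]


def ss_category(variant: IndelVariant, context: ProteinContext) -> str:
    """Secondary-structure location of the indel.

    The window is the site span widened by one residue on each side.  A
    homogeneous coil window is "coil"; a window mixing coil with exactly one
    non-coil state is the transition category "two"; otherwise the majority
    non-coil state wins, ties going to strand.
    """
    start, end = local_sequences(variant, context).site_span
    start = max(start - 1, 1)
    end = min(end + 1, context.length)
    window = context.secondary_structure[start - 1 : end]
    states = set(window)
    if states == {"coil"}:
        return "coil"
    if "coil" in states and len(states) == 2:
        return "two"
    n_helix = sum(1 for s in window if s == "helix")
    n_strand = sum(1 for s in window if s == "strand")
    return "strand" if n_strand >= n_helix else "helix"


def rip_category(variant: IndelVariant, context: ProteinContext) -> str:
    """Relative indel position: span midpoint over protein length, with the
    first and last 10% of the protein called N-/C-terminal."""
    if variant.kind == DELETION:
        midpoint = variant.position + (variant.length - 1) / 2.0
    else:
        midpoint = variant.position - 0.5
    r = midpoint / context.length
    if r <= 0.10:
        return "n_terminal"
    if r >= 0.90:
        return "c_terminal"
    return "middle"


def length_category(variant: IndelVariant) -> str:
    return "one" if variant.length == 1 else "more_than_one"


def pro_gly_flags(variant: IndelVariant) -> tuple[bool, bool]:
    return ("P" in variant.residues, "G" in variant.residues)


def _overlaps(span: tuple[int, int], intervals) -> bool:
    start, end = span
    return any(s <= end and start <= e for s, e in intervals)


def overlap_flags(
    variant: IndelVariant, context: ProteinContext
) -> dict[str, bool]:
    """Booleans for conserved_residue and each interval class, tested against
    the indel's site span (closed-interval intersection)."""
    span = local_sequences(variant, context).site_span
    flags = {
        "conserved_residue": any(
            context.conserved_residue[i - 1] for i in range(span[0], span[1] + 1)
        )
    }
    for cls in INTERVAL_CLASSES:
        flags[cls] = _overlaps(span, context.intervals(cls))
    return flags


def annotate_variant(
    variant: IndelVariant, context: ProteinContext
) -> dict[str, str]:
    """Assemble the complete categorical feature vector for one variant."""
    try:
        features: dict[str, str] = {}
        for name, flag in overlap_flags(variant, context).items():
            features[name] = _bool(flag)
        for mode in MODES:
            for prop in PROPERTIES:
                features[f"indel_{prop}_{mode}"] = indel_semantic(
                    variant.residues, prop, mode
                )
        local = local_sequences(variant, context)
        for mode in MODES:
            for scope in SCOPES:
                for prop in PROPERTIES:
                    d = indel_numeric(local.scope(scope), prop, mode) - indel_numeric(
                        variant.residues, prop, mode
                    )
                    features[
                        f"local_perturbation_{scope}_{prop}_{mode}"
                    ] = perturbation_category(d)
        features["probability_of_disorder"] = disorder_category(variant, context)
        features["rsa"] = rsa_category(variant, context)
        features["secondary_structure"] = ss_category(variant, context)
        features["relative_indel_position"] = rip_category(variant, context)
        features["indel_length"] = length_category(variant)
        has_p, has_g = pro_gly_flags(variant)
        features["has_proline"] = _bool(has_p)
        features["has_glycine"] = _bool(has_g)
    except AnnotationError:
        raise
    except Exception as exc:  # attach the variant id to low-level failures
        raise AnnotationError(
            f"failed to annotate {variant.protein_id} "
            f"{variant.kind} at {variant.position}: {exc}"
        ) from exc
    ANNOTATION_SCHEMA.validate_features(features)
    return features


def variant_id(variant: IndelVariant) -> str:
    return f"{variant.protein_id}:{variant.position}:{variant.kind}:{variant.residues}"


def annotate_all(
    variants: Iterable[IndelVariant],
    contexts: Mapping[str, ProteinContext],
) -> LabeledDataset:
    """Annotate a cohort into a feature table (labels carried through)."""
    records = []
    for variant in variants:
        try:
            context = contexts[variant.protein_id]
        except KeyError:
            raise AnnotationError(
                f"no protein context for {variant.protein_id!r}"
            ) from None
        records.append(
            Record(variant_id(variant), annotate_variant(variant, context), variant.label)
        )
    return LabeledDataset(ANNOTATION_SCHEMA, records)
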