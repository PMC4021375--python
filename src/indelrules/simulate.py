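"""Synthetic data: planted-rule feature tables and constructed protein contexts.

Two generators make the whole pipeline testable without any external data:

* ``generate_dataset`` draws categorical feature vectors from a background
  distribution and plants known literal conjunctions ("planted rules") that
  generate the deleterious class — negatives are rejection-sampled until
  they satisfy no planted rule, positives are forced (round-robin) to
  satisfy one.  With zero label noise the result is perfectly separable by
  the planted rules, which is the ground truth used for recovery tests.

* ``generate_protein_context`` builds a protein as a series of segments with
  designated secondary structure, disorder level, solvent accessibility and
  conservation, places annotation intervals, and emits variants positioned
  to hit requested feature combinations.

Both are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .datamodel import (
    AMINO_ACIDS,
    DELETERIOUS,
    DELETION,
    INSERTION,
    INTERVAL_CLASSES,
    NEUTRAL,
    FeatureSchema,
    IndelVariant,
    LabeledDataset,
    ProteinContext,
    Record,
    ValidationError,
)

_REJECTION_CAP = 10_000


@dataclass
class PlantedSpec:
    """Recipe for a planted-rule feature table.

    ``background_distribution`` maps parameter -> value probabilities
    (uniform where omitted).  ``label_noise_rate`` flips labels after
    construction.
    """

    schema: FeatureSchema
    planted_rules: list[dict[str, str]]
    n_pos: int
    n_neg: int
    seed: int
    label_noise_rate: float = 0.0
    background_distribution: Mapping[str, Sequence[float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_pos <= 0 or self.n_neg <= 0:
            raise ValidationError("n_pos and n_neg must be positive")
        if not 0.0 <= self.label_noise_rate < 1.0:
            raise ValidationError("label_noise_rate must lie in [0, 1)")
        if not self.planted_rules:
            raise ValidationError("at least one planted rule is required")
        for rule in self.planted_rules:
            if not rule:
                raise ValidationError("planted rules must have >= 1 literal")
            for p, v in rule.items():
                if v not in self.schema.values(p):
                    raise ValidationError(
                        f"planted literal {p}={v!r} not satisfiable under the schema"
                    )
        for p, probs in self.background_distribution.items():
            values = self.schema.values(p)
            if len(probs) != len(values):
                raise ValidationError(
                    f"background distribution for {p!r} has {len(probs)} "
                    f"probabilities for {len(values)} values"
                )
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ValidationError(f"background distribution for {p!r} invalid")


@dataclass
class GroundTruth:
    """Which planted rule generated each positive, and which labels flipped."""

    planted_rules: list[dict[str, str]]
    rule_of_positive: dict[str, int]
    flipped_ids: list[str]


def _satisfies(features: Mapping[str, str], rule: Mapping[str, str]) -> bool:
    return all(features.get(p) == v for p, v in rule.items())


def generate_dataset(spec: PlantedSpec) -> tuple[LabeledDataset, GroundTruth]:
    rng = np.random.default_rng(spec.seed)
    names = spec.schema.names

    def draw_background() -> dict[str, str]:
        features = {}
        for p in names:
            values = spec.schema.values(p)
            probs = spec.background_distribution.get(p)
            features[p] = str(rng.choice(values, p=probs))
        return features

    records: list[Record] = []
    rule_of_positive: dict[str, int] = {}
    for i in range(spec.n_pos):
        rule_idx = i % len(spec.planted_rules)
        features = draw_background()
        features.update(spec.planted_rules[rule_idx])
        vid = f"pos{i:05d}"
        rule_of_positive[vid] = rule_idx
        records.append(Record(vid, features, DELETERIOUS))
    for i in range(spec.n_neg):
        for _attempt in range(_REJECTION_CAP):
            features = draw_background()
            if not any(_satisfies(features, r) for r in spec.planted_rules):
                break
        else:
            raise ValidationError(
                "background distribution cannot avoid the planted rules "
                f"(rejection cap of {_REJECTION_CAP} attempts exceeded)"
            )
        records.append(Record(f"neg{i:05d}", features, NEUTRAL))

    flipped_ids: list[str] = []
    if spec.label_noise_rate > 0:
        flips = rng.random(len(records)) < spec.label_noise_rate
        flipped = []
        for rec, flip in zip(records, flips):
            if flip:
                flipped_ids.append(rec.variant_id)
                new_label = NEUTRAL if rec.label == DELETERIOUS else DELETERIOUS
                flipped.append(Record(rec.variant_id, rec.features, new_label))
            else:
                flipped.append(rec)
        records = flipped

    dataset = LabeledDataset(spec.schema, records)
    truth = GroundTruth(
        planted_rules=[dict(r) for r in spec.planted_rules],
        rule_of_positive=rule_of_positive,
        flipped_ids=flipped_ids,
    )
    return dataset, truth


def default_schema(n_parameters: int = 15, seed: int = 0) -> FeatureSchema:
    """A generic categorical schema: parameters p00..pNN with 2-4 values each.

    Value counts cycle 2, 3, 4 so the background is non-degenerate across
    arities, loosely emulating the mix of boolean flags and small ordinal
    scales in the real annotation schema.
    """
    params = []
    for i in range(n_parameters):
        arity = 2 + (i % 3)
        params.append((f"p{i:02d}", tuple(f"v{j}" for j in range(arity))))
    return FeatureSchema(params)


def default_planted_spec(seed: int, n_pos: int = 200, n_neg: int = 200) -> PlantedSpec:
    """The standard study condition for learner evaluation: 15 parameters,
    two planted three-literal rules, balanced 200+200 cohort, no label noise."""
    schema = default_schema(15)
    rules = [
        {"p00": "v1", "p04": "v2", "p08": "v3"},
        {"p02": "v0", "p07": "v1", "p11": "v2"},
    ]
    return PlantedSpec(
        schema=schema,
        planted_rules=rules,
        n_pos=n_pos,
        n_neg=n_neg,
        seed=seed,
    )


@dataclass(frozen=True)
class Segment:
    """A run of residues sharing structural character."""

    length: int
    ss: str = "coil"
    disorder: float = 0.5
    rsa: float = 75.0
    conserved: bool = False


@dataclass
class VariantRequest:
    kind: str
    position: int
    length: int = 1
    residues: str | None = None  # insertions only; deletions read the reference
    label: str = "unknown"


@dataclass
class ArchitectureSpec:
    """Blueprint of a synthetic protein: segments, intervals, variants.

    ``sequence`` (optional) overrides the random sequence, which is useful
    when a test needs exact physico-chemical codes at known positions.
    """

    protein_id: str
    segments: list[Segment]
    intervals: Mapping[str, Sequence[tuple[int, int]]] = field(default_factory=dict)
    variants: list[VariantRequest] = field(default_factory=list)
    sequence: str | None = None

    @property
    def length(self) -> int:
        return sum(s.length for s in self.segments)

    def __post_init__(self):
        if self.length < 30:
            raise ValidationError(
                f"synthetic proteins must be >= 30 residues, got {self.length}"
            )
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValidationError(
                "explicit sequence length does not match segment lengths"
            )
        for cls, ivals in self.intervals.items():
            if cls not in INTERVAL_CLASSES:
                raise ValidationError(f"unknown interval class {cls!r}")
            for start, end in ivals:
                if not 1 <= start <= end <= self.length:
                    raise ValidationError(
                        f"{cls} interval [{start}, {end}] exceeds protein "
                        f"length {self.length}"
                    )


def generate_protein_context(
    architecture: ArchitectureSpec, seed: int
) -> tuple[ProteinContext, list[IndelVariant]]:
    rng = np.random.default_rng(seed)
    if architecture.sequence is not None:
        sequence = architecture.sequence
    else:
        sequence = "".join(
            rng.choice(list(AMINO_ACIDS), size=architecture.length)
        )
    disorder: list[float] = []
    rsa: list[float] = []
    ss: list[str] = []
    conserved: list[bool] = []
    for seg in architecture.segments:
        disorder += [seg.disorder] * seg.length
        rsa += [seg.rsa] * seg.length
        ss += [seg.ss] * seg.length
        conserved += [seg.conserved] * seg.length
    intervals = {
        cls: tuple((int(s), int(e)) for s, e in architecture.intervals.get(cls, ()))
        for cls in INTERVAL_CLASSES
    }
    context = ProteinContext(
        protein_id=architecture.protein_id,
        sequence=sequence,
        disorder=tuple(disorder),
        rsa=tuple(rsa),
        secondary_structure=tuple(ss),
        conserved_residue=tuple(conserved),
        block_intervals=intervals["block"],
        pfam_intervals=intervals["pfam"],
        prosite_intervals=intervals["prosite"],
        uniprot_domain_intervals=intervals["uniprot_domain"],
        macsims_domain_intervals=intervals["macsims_domain"],
    )
    variants = []
    for req in architecture.variants:
        if req.kind == DELETION:
            residues = sequence[req.position - 1 : req.position - 1 + req.length]
        elif req.residues is not None:
            residues = req.residues
        else:
            residues = "".join(rng.choice(list(AMINO_ACIDS), size=req.length))
        variant = IndelVariant(
            protein_id=architecture.protein_id,
            position=req.position,
            kind=req.kind,
            residues=residues,
            label=req.label,
        )
        variant.validate_against(sequence)
        variants.append(variant)
    return context, variants
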