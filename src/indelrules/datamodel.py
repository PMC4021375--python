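"""Core records shared by every stage of the pipeline.

The tool operates entirely in protein space: a variant is a non-frameshift
indel (NFS-Indel) — an insertion or deletion of 1–6 whole amino acids — on a
reference protein sequence.  All coordinates are 1-based and intervals are
closed on both ends (matching the conventional residue numbering used in
variant nomenclature such as N526del).

Insertion semantics: ``position`` names the residue *before which* the new
residues are inserted, so valid insertion positions run from 1 to
``len(sequence) + 1``.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

INSERTION = "insertion"
DELETION = "deletion"

DELETERIOUS = "deleterious"
NEUTRAL = "neutral"
UNKNOWN = "unknown"
LABELS = (DELETERIOUS, NEUTRAL, UNKNOWN)

#: Longest indel considered, in residues.  The study scope is indels of
#: 3–18 base pairs, i.e. 1–6 amino acids; longer events are too rare to learn
#: from and are rejected by the readers.
MAX_INDEL_RESIDUES = 6

SS_STATES = ("helix", "strand", "coil")


class IndelRulesError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(IndelRulesError):
    """A record violates a domain invariant."""


class FormatError(IndelRulesError):
    """An input file is malformed.

    Carries enough context (file, line, field) for the user to locate the
    problem; readers reject rather than silently coerce.
    """

    def __init__(self, message: str, *, path=None, line=None, field_name=None):
        parts = []
        if path is not None:
            parts.append(f"{path}")
        if line is not None:
            parts.append(f"line {line}")
        if field_name is not None:
            parts.append(f"field '{field_name}'")
        prefix = ", ".join(parts)
        super().__init__(f"{prefix}: {message}" if prefix else message)
        self.path = path
        self.line = line
        self.field_name = field_name


class SchemaError(IndelRulesError):
    """A feature vector or literal does not conform to the parameter schema."""


class AnnotationError(IndelRulesError):
    """A variant cannot be annotated from its protein context."""


def _check_residues(residues: str) -> None:
    if not residues:
        raise ValidationError("residue string is empty")
    for i, aa in enumerate(residues, start=1):
        if aa not in AMINO_ACIDS:
            raise ValidationError(
                f"non-standard residue {aa!r} at position {i} of {residues!r}"
            )


@dataclass(frozen=True)
class IndelVariant:
    """One NFS-Indel on a reference protein.

    ``residues`` holds the inserted residues (insertion) or the deleted
    reference residues (deletion).
    """

    protein_id: str
    position: int
    kind: str
    residues: str
    label: str = UNKNOWN

    def __post_init__(self):
        if self.kind not in (INSERTION, DELETION):
            raise ValidationError(f"unknown variant kind {self.kind!r}")
        if self.label not in LABELS:
            raise ValidationError(f"unknown label token {self.label!r}")
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")
        _check_residues(self.residues)
        if len(self.residues) > MAX_INDEL_RESIDUES:
            raise ValidationError(
                f"indel of {len(self.residues)} residues is outside the "
                f"supported range of 3-18 base pairs (1-{MAX_INDEL_RESIDUES} "
                f"amino acids)"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def validate_against(self, sequence: str) -> None:
        """Check the positional invariants against the reference sequence."""
        n = self.length
        if self.kind == DELETION:
            if self.position + n - 1 > len(sequence):
                raise ValidationError(
                    f"{self.protein_id}: deletion span "
                    f"[{self.position}, {self.position + n - 1}] exceeds "
                    f"protein length {len(sequence)}"
                )
            ref = sequence[self.position - 1 : self.position - 1 + n]
            if ref != self.residues:
                raise ValidationError(
                    f"{self.protein_id}: deleted residues {self.residues!r} do "
                    f"not match reference {ref!r} at position {self.position}"
                )
        else:
            if self.position > len(sequence) + 1:
                raise ValidationError(
                    f"{self.protein_id}: insertion position {self.position} "
                    f"exceeds protein length {len(sequence)} + 1"
                )


Interval = tuple[int, int]


def _check_intervals(name: str, intervals: Sequence[Interval], length: int) -> None:
    for start, end in intervals:
        if not (1 <= start <= end <= length):
            raise ValidationError(
                f"{name} interval [{start}, {end}] out of bounds for protein "
                f"of length {length}"
            )


@dataclass(frozen=True)
class ProteinContext:
    """A protein sequence plus the per-residue tracks and annotated intervals
    needed to compute the categorical features.

    Per-residue tracks (all of length ``len(sequence)``): ``disorder`` is the
    probability P that the residue lies in a disordered region; ``rsa`` is the
    residue solvent-accessible surface value R_v; ``secondary_structure`` is
    one of helix/strand/coil; ``conserved_residue`` flags residues conserved
    in the protein family alignment.  Interval lists are closed and 1-based.
    """

    protein_id: str
    sequence: str
    disorder: tuple[float, ...]
    rsa: tuple[float, ...]
    secondary_structure: tuple[str, ...]
    conserved_residue: tuple[bool, ...]
    block_intervals: tuple[Interval, ...] = ()
    pfam_intervals: tuple[Interval, ...] = ()
    prosite_intervals: tuple[Interval, ...] = ()
    uniprot_domain_intervals: tuple[Interval, ...] = ()
    macsims_domain_intervals: tuple[Interval, ...] = ()

    def __post_init__(self):
        _check_residues(self.sequence)
        n = len(self.sequence)
        for track in ("disorder", "rsa", "secondary_structure", "conserved_residue"):
            values = getattr(self, track)
            if len(values) != n:
                raise ValidationError(
                    f"{self.protein_id}: track '{track}' has {len(values)} "
                    f"entries for a protein of length {n}"
                )
        for p in self.disorder:
            if not 0.0 <= p <= 1.0:
                raise ValidationError(
                    f"{self.protein_id}: disorder probability {p} outside [0, 1]"
                )
        for r in self.rsa:
            if r < 0:
                raise ValidationError(f"{self.protein_id}: negative RSA value {r}")
        for s in self.secondary_structure:
            if s not in SS_STATES:
                raise ValidationError(
                    f"{self.protein_id}: unknown secondary-structure state {s!r}"
                )
        for name in (
            "block_intervals",
            "pfam_intervals",
            "prosite_intervals",
            "uniprot_domain_intervals",
            "macsims_domain_intervals",
        ):
            _check_intervals(f"{self.protein_id}: {name}", getattr(self, name), n)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def intervals(self, feature_class: str) -> tuple[Interval, ...]:
        return getattr(self, f"{feature_class}_intervals")


INTERVAL_CLASSES = ("block", "pfam", "prosite", "uniprot_domain", "macsims_domain")


class FeatureSchema:
    """Ordered mapping from parameter name to its allowed categorical values."""

    def __init__(self, parameters: Iterable[tuple[str, Sequence[str]]]):
        self._params: "OrderedDict[str, tuple[str, ...]]" = OrderedDict()
        for name, values in parameters:
            if name in self._params:
                raise SchemaError(f"duplicate parameter {name!r}")
            values = tuple(values)
            if len(values) < 2 or len(set(values)) != len(values):
                raise SchemaError(
                    f"parameter {name!r} needs >= 2 distinct values, got {values}"
                )
            self._params[name] = values

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._params)

    def values(self, name: str) -> tuple[str, ...]:
        try:
            return self._params[name]
        except KeyError:
            raise SchemaError(f"unknown parameter {name!r}") from None

    def index(self, name: str) -> int:
        try:
            return list(self._params).index(name)
        except ValueError:
            raise SchemaError(f"unknown parameter {name!r}") from None

    def items(self) -> Iterable[tuple[str, tuple[str, ...]]]:
        return self._params.items()

    def subset(self, names: Sequence[str]) -> "FeatureSchema":
        return FeatureSchema((n, self.values(n)) for n in names)

    def validate_features(self, features: Mapping[str, str], where: str = "") -> None:
        ctx = f" ({where})" if where else ""
        missing = set(self._params) - set(features)
        if missing:
            raise SchemaError(f"missing parameters {sorted(missing)}{ctx}")
        extra = set(features) - set(self._params)
        if extra:
            raise SchemaError(f"unknown parameters {sorted(extra)}{ctx}")
        for name, value in features.items():
            if value not in self._params[name]:
                raise SchemaError(
                    f"value {value!r} not allowed for parameter {name!r}{ctx}"
                )

    def __contains__(self, name: str) -> bool:
        return name in self._params

    def __len__(self) -> int:
        return len(self._params)

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureSchema) and self._params == other._params

    def __repr__(self) -> str:
        return f"FeatureSchema({len(self._params)} parameters)"


class Record(NamedTuple):
    """One example: a variant id, its categorical feature vector, its label."""

    variant_id: str
    features: Mapping[str, str]
    label: str


@dataclass
class LabeledDataset:
    """A feature table: one fully-populated categorical vector per variant.

    Training operations require every record to be labelled deleterious or
    neutral; the readers additionally accept the token ``unknown`` so that
    cohorts awaiting prediction can flow through the same format
    (``two_class`` guards the training entry points).
    """

    schema: FeatureSchema
    records: list[Record]

    def __post_init__(self):
        seen = set()
        for rec in self.records:
            if rec.variant_id in seen:
                raise ValidationError(f"duplicate variant id {rec.variant_id!r}")
            seen.add(rec.variant_id)
            if rec.label not in LABELS:
                raise ValidationError(
                    f"{rec.variant_id}: unknown label token {rec.label!r}"
                )
            self.schema.validate_features(rec.features, where=rec.variant_id)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def positives(self) -> list[Record]:
        return [r for r in self.records if r.label == DELETERIOUS]

    @property
    def negatives(self) -> list[Record]:
        return [r for r in self.records if r.label == NEUTRAL]

    def two_class(self) -> "LabeledDataset":
        """Return self after checking no record is unlabelled."""
        unknown = [r.variant_id for r in self.records if r.label == UNKNOWN]
        if unknown:
            raise ValidationError(
                f"{len(unknown)} records have label 'unknown' "
                f"(first: {unknown[0]}); training requires two classes"
            )
        return self

    def restrict(self, parameter_names: Sequence[str]) -> "LabeledDataset":
        """Project onto a parameter subset (order taken from the argument)."""
        sub = self.schema.subset(parameter_names)
        records = [
            Record(r.variant_id, {p: r.features[p] for p in parameter_names}, r.label)
            for r in self.records
        ]
        return LabeledDataset(sub, records)

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(self.schema, [self.records[i] for i in indices])

    def to_frame(self):
        """Return the table as a pandas DataFrame indexed by variant id."""
        import pandas as pd

        data = {
            "label": [r.label for r in self.records],
        }
        for name in self.schema.names:
            data[name] = [r.features[name] for r in self.records]
        return pd.DataFrame(data, index=[r.variant_id for r in self.records])


@dataclass(frozen=True)
class RunConfig:
    """Tunable knobs of the learning pipeline.

    ``minpos``/``noise`` are the rule-acceptance constraints: the minimum
    number of positive training examples a rule must cover and the maximum
    number of negatives it may cover.  The defaults (minpos=6, noise=0)
    eliminate false-positive training coverage at the cost of rule
    generality.  ``correlation_cutoff`` and ``x_cutoff`` drive parameter
    selection; ``beam_width``/``max_literals`` bound the rule search.
    """

    minpos: int = 6
    noise: int = 0
    correlation_cutoff: float = 0.7
    x_cutoff: float = 0.2
    folds: int = 10
    seed: int | None = None
    beam_width: int = 5
    max_literals: int = 6

    def __post_init__(self):
        if self.minpos < 1:
            raise ValidationError("minpos must be a positive integer")
        if self.noise < 0:
            raise ValidationError("noise must be non-negative")
        if not 0.0 <= self.correlation_cutoff <= 1.0:
            raise ValidationError("correlation_cutoff must lie in [0, 1]")
        if self.x_cutoff < 0:
            raise ValidationError("x_cutoff must be non-negative")
        if self.folds < 2:
            raise ValidationError("folds must be >= 2")
        if self.beam_width < 1 or self.max_literals < 1:
            raise ValidationError("beam_width and max_literals must be positive")

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValidationError(
                "a seed is required for stochastic operations; set RunConfig.seed"
            )
        return int(self.seed)

    def with_overrides(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        extra = set(data) - known
        if extra:
            raise ValidationError(f"unknown configuration keys {sorted(extra)}")
        return cls(**dict(data))
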