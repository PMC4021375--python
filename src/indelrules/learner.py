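"""Sequential-covering induction of deleterious-classification rules.

The learner is a propositional specialisation of bottom-clause guided ILP
search: every example is fully described by single-valued categorical
attributes, so the bottom clause of a seed example reduces to its set of
(parameter, value) pairs, and rule growth is a beam search over conjunctions
of literals drawn from that set.

A candidate rule is scored by (positives covered − negatives covered) on the
full training set.  A rule is acceptable when it covers at least ``minpos``
positives and at most ``noise`` negatives; with the default noise=0 every
accepted rule has 100% precision on its training data.  The outer loop picks
uncovered positive examples (in an order shuffled under the run seed) as
seeds, grows one rule per seed, removes the positives the accepted rule
covers, and stops when every positive is covered or no remaining seed yields
an acceptable rule.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .datamodel import (
    DELETERIOUS,
    FeatureSchema,
    LabeledDataset,
    Record,
    RunConfig,
    SchemaError,
    ValidationError,
)

Literal = tuple[str, str]


@dataclass(frozen=True)
class Rule:
    """A conjunction of (parameter, value) literals predicting 'deleterious'."""

    literals: tuple[Literal, ...]
    train_pos_covered: int = 0
    train_neg_covered: int = 0
    seed_example_id: str = ""

    def __post_init__(self):
        if not self.literals:
            raise ValidationError("a rule needs at least one literal")
        params = [p for p, _ in self.literals]
        if len(set(params)) != len(params):
            raise ValidationError("at most one literal per parameter")

    @property
    def score(self) -> int:
        return self.train_pos_covered - self.train_neg_covered

    def as_text(self) -> str:
        body = ", ".join(f"{p} (A, {v})" for p, v in self.literals)
        return f"deleterious (A) if {body}."


@dataclass
class RuleSet:
    """An ordered list of rules plus the schema and config they were learned under."""

    rules: list[Rule]
    schema: FeatureSchema
    config: RunConfig = field(default_factory=RunConfig)

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)


def covers(rule: Rule, features: Mapping[str, str]) -> bool:
    """True iff every literal of the rule holds in the feature vector."""
    for param, value in rule.literals:
        if param not in features:
            raise SchemaError(f"rule literal references unknown parameter {param!r}")
        if features[param] != value:
            return False
    return True


def _coverage(rule: Rule, records: Sequence[Record]) -> list[Record]:
    return [r for r in records if covers(rule, r.features)]


def grow_rule(
    seed_example: Record,
    dataset: LabeledDataset,
    config: RunConfig,
    parameters: Sequence[str] | None = None,
) -> Rule | None:
    """Grow one rule from a positive seed example by beam search.

    Candidate literals are restricted to the (parameter, value) pairs true of
    the seed (the propositional bottom clause).  States whose negative
    coverage already satisfies the noise bound are not specialised further;
    states that can no longer reach ``minpos`` positives are pruned.  Returns
    the best acceptable rule — maximum score, ties broken by fewer literals,
    then by schema order of the literals — or None if no conjunction over
    seed-true literals is acceptable.
    """
    if seed_example.label != DELETERIOUS:
        raise ValidationError(
            f"seed example {seed_example.variant_id} is not a positive"
        )
    names = tuple(parameters) if parameters is not None else dataset.schema.names
    candidates: list[Literal] = [(p, seed_example.features[p]) for p in names]

    pos = dataset.positives
    neg = dataset.negatives
    feats_pos = [r.features for r in pos]
    feats_neg = [r.features for r in neg]

    # state: (literal index frozenset, covered positive indices, covered negative indices)
    start = (frozenset(), frozenset(range(len(pos))), frozenset(range(len(neg))))
    beam: list[tuple[frozenset, frozenset, frozenset]] = [start]
    best: tuple | None = None  # (neg score, n literals, sorted indices, state)

    def consider(lits: frozenset, pc: frozenset, nc: frozenset) -> None:
        nonlocal best
        if not lits or len(pc) < config.minpos or len(nc) > config.noise:
            return
        key = (-(len(pc) - len(nc)), len(lits), tuple(sorted(lits)))
        if best is None or key < best[0]:
            best = (key, (lits, pc, nc))

    for _depth in range(config.max_literals):
        expansions: dict[frozenset, tuple[frozenset, frozenset]] = {}
        for lits, pc, nc in beam:
            for idx in range(len(candidates)):
                if idx in lits:
                    continue
                new_lits = lits | {idx}
                if new_lits in expansions:
                    continue
                p, v = candidates[idx]
                new_pc = frozenset(i for i in pc if feats_pos[i][p] == v)
                if len(new_pc) < config.minpos:
                    continue
                new_nc = frozenset(i for i in nc if feats_neg[i][p] == v)
                expansions[new_lits] = (new_pc, new_nc)
        if not expansions:
            break
        states = [(lits, pc, nc) for lits, (pc, nc) in expansions.items()]
        for lits, pc, nc in states:
            consider(lits, pc, nc)
        # keep specialising only states still violating the noise bound
        open_states = [
            (lits, pc, nc) for lits, pc, nc in states if len(nc) > config.noise
        ]
        open_states.sort(
            key=lambda s: (-(len(s[1]) - len(s[2])), len(s[0]), tuple(sorted(s[0])))
        )
        beam = open_states[: config.beam_width]
        if not beam:
            break

    if best is None:
        return None
    lits, pc, nc = best[1]
    literals = tuple(candidates[i] for i in sorted(lits))
    return Rule(
        literals=literals,
        train_pos_covered=len(pc),
        train_neg_covered=len(nc),
        seed_example_id=seed_example.variant_id,
    )


def learn(
    dataset: LabeledDataset,
    config: RunConfig,
    parameters: Sequence[str] | None = None,
) -> RuleSet:
    """Learn a rule set by sequential covering.

    Deterministic given (dataset, config, parameters): the seed-example order
    is shuffled under ``config.seed``.  Rules whose covered positive set is a
    subset of an earlier rule's are discarded as redundant.
    """
    dataset.two_class()
    pos = dataset.positives
    if not pos:
        raise ValidationError("cannot learn: no positive (deleterious) examples")
    seed = config.require_seed()
    order = list(range(len(pos)))
    random.Random(seed).shuffle(order)

    rules: list[Rule] = []
    covered_sets: list[frozenset[str]] = []
    covered: set[str] = set()
    for i in order:
        seed_rec = pos[i]
        if seed_rec.variant_id in covered:
            continue
        rule = grow_rule(seed_rec, dataset, config, parameters)
        if rule is None:
            continue
        pos_ids = frozenset(r.variant_id for r in _coverage(rule, pos))
        if any(pos_ids <= earlier for earlier in covered_sets):
            continue
        rules.append(rule)
        covered_sets.append(pos_ids)
        covered |= pos_ids
        if len(covered) == len(pos):
            break
    schema = (
        dataset.schema if parameters is None else dataset.schema.subset(parameters)
    )
    return RuleSet(rules=rules, schema=schema, config=config)
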