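"""Shared fixtures: tiny protein contexts and dataset builders."""

import pytest

from indelrules.datamodel import (
    FeatureSchema,
    LabeledDataset,
    ProteinContext,
    Record,
)


def make_context(
    sequence,
    protein_id="P1",
    disorder=0.1,
    rsa=10.0,
    ss="coil",
    conserved=False,
    **intervals,
):
    """A context with constant tracks unless per-residue lists are given."""
    n = len(sequence)

    def track(value):
        return tuple(value) if isinstance(value, (list, tuple)) else (value,) * n

    return ProteinContext(
        protein_id=protein_id,
        sequence=sequence,
        disorder=track(disorder),
        rsa=track(rsa),
        secondary_structure=track(ss),
        conserved_residue=track(conserved),
        **{f"{cls}_intervals": tuple(iv) for cls, iv in intervals.items()},
    )


def make_dataset(columns, labels, schema=None):
    """Build a LabeledDataset from parallel value columns.

    ``columns`` maps parameter name -> list of values (one per record);
    ``labels`` is the matching label list.
    """
    names = list(columns)
    n = len(labels)
    if schema is None:
        schema = FeatureSchema(
            (p, tuple(sorted(set(columns[p])))) for p in names
        )
    records = [
        Record(f"r{i:04d}", {p: columns[p][i] for p in names}, labels[i])
        for i in range(n)
    ]
    return LabeledDataset(schema, records)


@pytest.fixture
def toy_context():
    return make_context("MKVANQW")
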