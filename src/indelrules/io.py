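"""Readers and writers for the file formats the tool consumes and emits.

All tabular formats are UTF-8, tab-separated, with '#' comment lines.
Coordinates are 1-based, intervals closed.  Readers reject invalid input
with errors naming the file, line and field; nothing is silently coerced.

Formats:

* FASTA — reference protein sequences (read via Biopython).
* variants TSV — columns protein_id, position, kind, residues, label.
* tracks TSV — per-residue columns protein_id, residue_index, disorder,
  rsa, secondary_structure, conserved; one row per residue.
* intervals TSV — columns protein_id, feature_class, start, end.
* feature table TSV — the categorical schema as '# parameter' comment
  lines, then variant_id, label and one column per parameter; round-trips
  losslessly.
* rule sets — lossless JSON, plus a human-oriented text rendering in the
  classic rule style ("deleterious (A) if block (A, true), ...").
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Mapping, Sequence

import yaml
from Bio import SeqIO

from .datamodel import (
    AMINO_ACIDS,
    INTERVAL_CLASSES,
    LABELS,
    MAX_INDEL_RESIDUES,
    SS_STATES,
    FeatureSchema,
    FormatError,
    IndelVariant,
    LabeledDataset,
    ProteinContext,
    Record,
    RunConfig,
    SchemaError,
    ValidationError,
)
from .learner import Rule, RuleSet

VARIANT_COLUMNS = ("protein_id", "position", "kind", "residues", "label")
TRACK_COLUMNS = (
    "protein_id",
    "residue_index",
    "disorder",
    "rsa",
    "secondary_structure",
    "conserved",
)
INTERVAL_COLUMNS = ("protein_id", "feature_class", "start", "end")


def read_fasta(path) -> dict[str, str]:
    """Read protein sequences; ids must be unique, residues standard."""
    path = Path(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"duplicate id {record.id!r}", path=path)
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for {record.id!r}", path=path)
        for i, aa in enumerate(seq, start=1):
            if aa not in AMINO_ACIDS:
                raise FormatError(
                    f"non-standard residue {aa!r} at position {i} of "
                    f"record {record.id!r}",
                    path=path,
                )
        sequences[record.id] = seq
    if not sequences:
        raise FormatError("no FASTA records found", path=path)
    return sequences


def _tsv_rows(path: Path, columns: Sequence[str]):
    """Yield (line_number, dict) for each data row of a headered TSV."""
    with open(path, newline="", encoding="utf-8") as handle:
        header: list[str] | None = None
        for line_no, line in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not line or (line[0].startswith("#")):
                continue
            if header is None:
                header = [c.strip() for c in line]
                missing = set(columns) - set(header)
                if missing:
                    raise FormatError(
                        f"missing columns {sorted(missing)}", path=path, line=line_no
                    )
                continue
            if len(line) != len(header):
                raise FormatError(
                    f"expected {len(header)} fields, found {len(line)}",
                    path=path,
                    line=line_no,
                )
            yield line_no, dict(zip(header, line))
        if header is None:
            raise FormatError("empty file (no header)", path=path)


def _parse_int(row, key, path, line_no) -> int:
    try:
        return int(row[key])
    except ValueError:
        raise FormatError(
            f"not an integer: {row[key]!r}", path=path, line=line_no, field_name=key
        ) from None


def _parse_float(row, key, path, line_no) -> float:
    try:
        return float(row[key])
    except ValueError:
        raise FormatError(
            f"not a number: {row[key]!r}", path=path, line=line_no, field_name=key
        ) from None


def read_variants(path, contexts: Mapping[str, object]) -> list[IndelVariant]:
    """Read the variant table and validate each row against its protein.

    ``contexts`` maps protein_id to either a ProteinContext or a plain
    sequence string.
    """
    path = Path(path)
    variants = []
    for line_no, row in _tsv_rows(path, VARIANT_COLUMNS):
        protein_id = row["protein_id"]
        if protein_id not in contexts:
            raise FormatError(
                f"unknown protein id {protein_id!r}",
                path=path,
                line=line_no,
                field_name="protein_id",
            )
        ctx = contexts[protein_id]
        sequence = ctx if isinstance(ctx, str) else ctx.sequence
        residues = row["residues"].upper()
        if len(residues) > MAX_INDEL_RESIDUES:
            raise FormatError(
                f"indel of {len(residues)} residues exceeds the supported "
                f"range of 3-18 base pairs (1-{MAX_INDEL_RESIDUES} amino acids)",
                path=path,
                line=line_no,
                field_name="residues",
            )
        if row["label"] not in LABELS:
            raise FormatError(
                f"unknown label token {row['label']!r}",
                path=path,
                line=line_no,
                field_name="label",
            )
        try:
            variant = IndelVariant(
                protein_id=protein_id,
                position=_parse_int(row, "position", path, line_no),
                kind=row["kind"],
                residues=residues,
                label=row["label"],
            )
            variant.validate_against(sequence)
        except ValidationError as exc:
            raise FormatError(str(exc), path=path, line=line_no) from exc
        variants.append(variant)
    return variants


def write_variants(variants: Sequence[IndelVariant], path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(VARIANT_COLUMNS) + "\n")
        for v in variants:
            handle.write(
                f"{v.protein_id}\t{v.position}\t{v.kind}\t{v.residues}\t{v.label}\n"
            )


def read_tracks(
    tracks_path, intervals_path, sequences: Mapping[str, str]
) -> dict[str, ProteinContext]:
    """Assemble ProteinContexts from a per-residue track file and an interval file."""
    tracks_path = Path(tracks_path)
    per_protein: dict[str, dict[int, dict]] = {}
    for line_no, row in _tsv_rows(tracks_path, TRACK_COLUMNS):
        pid = row["protein_id"]
        if pid not in sequences:
            raise FormatError(
                f"unknown protein id {pid!r}",
                path=tracks_path,
                line=line_no,
                field_name="protein_id",
            )
        idx = _parse_int(row, "residue_index", tracks_path, line_no)
        disorder = _parse_float(row, "disorder", tracks_path, line_no)
        if not 0.0 <= disorder <= 1.0:
            raise FormatError(
                f"disorder probability {disorder} outside [0, 1]",
                path=tracks_path,
                line=line_no,
                field_name="disorder",
            )
        rsa = _parse_float(row, "rsa", tracks_path, line_no)
        if rsa < 0:
            raise FormatError(
                f"negative RSA value {rsa}",
                path=tracks_path,
                line=line_no,
                field_name="rsa",
            )
        ss = row["secondary_structure"]
        if ss not in SS_STATES:
            raise FormatError(
                f"unknown secondary-structure state {ss!r}",
                path=tracks_path,
                line=line_no,
                field_name="secondary_structure",
            )
        flag = row["conserved"].lower()
        if flag not in ("true", "false"):
            raise FormatError(
                f"conserved flag must be true/false, got {row['conserved']!r}",
                path=tracks_path,
                line=line_no,
                field_name="conserved",
            )
        rows = per_protein.setdefault(pid, {})
        if idx in rows:
            raise FormatError(
                f"duplicate residue index {idx} for {pid!r}",
                path=tracks_path,
                line=line_no,
            )
        rows[idx] = {
            "disorder": disorder,
            "rsa": rsa,
            "ss": ss,
            "conserved": flag == "true",
        }

    intervals_path = Path(intervals_path)
    per_protein_intervals: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for line_no, row in _tsv_rows(intervals_path, INTERVAL_COLUMNS):
        pid = row["protein_id"]
        if pid not in sequences:
            raise FormatError(
                f"unknown protein id {pid!r}",
                path=intervals_path,
                line=line_no,
                field_name="protein_id",
            )
        cls = row["feature_class"]
        if cls not in INTERVAL_CLASSES:
            raise FormatError(
                f"unknown feature class {cls!r} "
                f"(expected one of {', '.join(INTERVAL_CLASSES)})",
                path=intervals_path,
                line=line_no,
                field_name="feature_class",
            )
        start = _parse_int(row, "start", intervals_path, line_no)
        end = _parse_int(row, "end", intervals_path, line_no)
        if not 1 <= start <= end <= len(sequences[pid]):
            raise FormatError(
                f"interval [{start}, {end}] out of bounds for {pid!r} "
                f"of length {len(sequences[pid])}",
                path=intervals_path,
                line=line_no,
            )
        per_protein_intervals.setdefault(pid, {}).setdefault(cls, []).append(
            (start, end)
        )

    contexts: dict[str, ProteinContext] = {}
    for pid, sequence in sequences.items():
        rows = per_protein.get(pid)
        if rows is None:
            continue
        expected = set(range(1, len(sequence) + 1))
        if set(rows) != expected:
            raise FormatError(
                f"{pid!r}: track covers {len(rows)} residues but the protein "
                f"has {len(sequence)}",
                path=tracks_path,
            )
        ordered = [rows[i] for i in range(1, len(sequence) + 1)]
        ivals = per_protein_intervals.get(pid, {})
        contexts[pid] = ProteinContext(
            protein_id=pid,
            sequence=sequence,
            disorder=tuple(r["disorder"] for r in ordered),
            rsa=tuple(r["rsa"] for r in ordered),
            secondary_structure=tuple(r["ss"] for r in ordered),
            conserved_residue=tuple(r["conserved"] for r in ordered),
            block_intervals=tuple(ivals.get("block", ())),
            pfam_intervals=tuple(ivals.get("pfam", ())),
            prosite_intervals=tuple(ivals.get("prosite", ())),
            uniprot_domain_intervals=tuple(ivals.get("uniprot_domain", ())),
            macsims_domain_intervals=tuple(ivals.get("macsims_domain", ())),
        )
    return contexts


def write_tracks(contexts: Mapping[str, ProteinContext], tracks_path, intervals_path):
    with open(tracks_path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(TRACK_COLUMNS) + "\n")
        for ctx in contexts.values():
            for i in range(ctx.length):
                handle.write(
                    f"{ctx.protein_id}\t{i + 1}\t{ctx.disorder[i]:g}\t"
                    f"{ctx.rsa[i]:g}\t{ctx.secondary_structure[i]}\t"
                    f"{'true' if ctx.conserved_residue[i] else 'false'}\n"
                )
    with open(intervals_path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(INTERVAL_COLUMNS) + "\n")
        for ctx in contexts.values():
            for cls in INTERVAL_CLASSES:
                for start, end in ctx.intervals(cls):
                    handle.write(f"{ctx.protein_id}\t{cls}\t{start}\t{end}\n")


# --- feature tables ---------------------------------------------------------

_SCHEMA_PREFIX = "# parameter"


def write_feature_table(dataset: LabeledDataset, path) -> None:
    """Write the feature table with its schema embedded as comment lines."""
    path = Path(path)
    names = dataset.schema.names
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("# indel feature table\n")
        for name, values in dataset.schema.items():
            handle.write(f"{_SCHEMA_PREFIX}\t{name}\t{'|'.join(values)}\n")
        handle.write("\t".join(("variant_id", "label") + names) + "\n")
        for rec in dataset.records:
            row = [rec.variant_id, rec.label] + [rec.features[p] for p in names]
            handle.write("\t".join(row) + "\n")


def read_feature_table(path) -> LabeledDataset:
    """Read a feature table; inverse of ``write_feature_table``."""
    path = Path(path)
    params: list[tuple[str, tuple[str, ...]]] = []
    header: list[str] | None = None
    records: list[Record] = []
    with open(path, newline="", encoding="utf-8") as handle:
        for line_no, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(_SCHEMA_PREFIX + "\t"):
                parts = line.split("\t")
                if len(parts) != 3:
                    raise FormatError(
                        "malformed schema line", path=path, line=line_no
                    )
                params.append((parts[1], tuple(parts[2].split("|"))))
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header[:2] != ["variant_id", "label"]:
                    raise FormatError(
                        "header must start with variant_id, label",
                        path=path,
                        line=line_no,
                    )
                if not params:
                    raise FormatError(
                        "no schema comment lines before the header", path=path
                    )
                schema_names = [name for name, _ in params]
                if header[2:] != schema_names:
                    raise FormatError(
                        "data columns do not match the declared schema",
                        path=path,
                        line=line_no,
                    )
                continue
            if len(fields) != len(header):
                raise FormatError(
                    f"expected {len(header)} fields, found {len(fields)}",
                    path=path,
                    line=line_no,
                )
            features = dict(zip(header[2:], fields[2:]))
            records.append(Record(fields[0], features, fields[1]))
    if header is None:
        raise FormatError("no header row found", path=path)
    try:
        schema = FeatureSchema(params)
        return LabeledDataset(schema, records)
    except (ValidationError, SchemaError) as exc:
        raise FormatError(str(exc), path=path) from exc


# --- rule sets --------------------------------------------------------------


def write_rules(ruleset: RuleSet, path, format: str = "json") -> None:
    """Write a rule set: 'json' round-trips losslessly, 'text' is for humans."""
    path = Path(path)
    if format == "json":
        payload = {
            "config": ruleset.config.to_dict(),
            "schema": {name: list(vals) for name, vals in ruleset.schema.items()},
            "rules": [
                {
                    "literals": [[p, v] for p, v in rule.literals],
                    "train_pos_covered": rule.train_pos_covered,
                    "train_neg_covered": rule.train_neg_covered,
                    "seed_example_id": rule.seed_example_id,
                }
                for rule in ruleset.rules
            ],
        }
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=2)
            handle.write("\n")
    elif format == "text":
        with open(path, "w", encoding="utf-8") as handle:
            for i, rule in enumerate(ruleset.rules, start=1):
                handle.write(
                    f"# rule {i}: pos_covered={rule.train_pos_covered}, "
                    f"neg_covered={rule.train_neg_covered}\n"
                )
                handle.write(rule.as_text() + "\n")
    else:
        raise ValidationError(f"unknown rule format {format!r}")


def read_rules(path) -> RuleSet:
    """Read a JSON rule set (the text rendering is write-only)."""
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as handle:
            payload = json.load(handle)
        schema = FeatureSchema(
            (name, tuple(vals)) for name, vals in payload["schema"].items()
        )
        config = RunConfig.from_dict(payload["config"])
        rules = [
            Rule(
                literals=tuple((p, v) for p, v in entry["literals"]),
                train_pos_covered=int(entry["train_pos_covered"]),
                train_neg_covered=int(entry["train_neg_covered"]),
                seed_example_id=str(entry["seed_example_id"]),
            )
            for entry in payload["rules"]
        ]
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise FormatError(f"malformed rule file: {exc}", path=path) from exc
    return RuleSet(rules=rules, schema=schema, config=config)


# --- configuration ----------------------------------------------------------


def read_config(path) -> RunConfig:
    path = Path(path)
    with open(path, encoding="utf-8") as handle:
        data = yaml.safe_load(handle) or {}
    if not isinstance(data, dict):
        raise FormatError("configuration must be a YAML mapping", path=path)
    try:
        return RunConfig.from_dict(data)
    except (ValidationError, TypeError) as exc:
        raise FormatError(str(exc), path=path) from exc
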