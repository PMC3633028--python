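"""Readers and writers: CSV/TSV cohorts, YAML schemas, JSON rule files.

A cohort is a delimited text table with a header; the attribute typing
lives in a small YAML config::

    outcome: Outcome
    attributes:
      INSS: {kind: nominal, values: ["1", "2", "3", "4", "4s"]}
      Age:  {kind: ordered, low: 0.0, high: 25.0}

Rule files are JSON: a list of objects, one per rule, carrying the id,
the rule text in the grammar, and (when available) the training
statistics.  Parsing the text back recovers the exact rule, so the file
is both machine- and human-readable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .rules import Classifier, Rule, RuleStats, format_rule, parse_rule
from .schema import AttributeSchema, CohortDataset, SchemaError, nominal, ordered


def schema_from_dict(config: dict) -> tuple[list[AttributeSchema], str]:
    try:
        outcome = config["outcome"]
        attrs = config["attributes"]
    except KeyError as exc:
        raise SchemaError(f"schema config lacks the {exc.args[0]!r} key")
    known_keys = {"outcome", "attributes"}
    extra = set(config) - known_keys
    if extra:
        raise SchemaError(f"unknown schema config keys: {sorted(extra)}")
    schema = []
    for name, decl in attrs.items():
        kind = decl.get("kind")
        if kind == "nominal":
            schema.append(nominal(name, [str(v) for v in decl["values"]]))
        elif kind == "ordered":
            schema.append(ordered(name, decl["low"], decl["high"]))
        else:
            raise SchemaError(f"attribute {name!r}: unknown kind {kind!r}")
    return schema, str(outcome)


def schema_to_dict(schema: Sequence[AttributeSchema], outcome: str) -> dict:
    attrs = {}
    for a in schema:
        if a.kind == "nominal":
            attrs[a.name] = {"kind": "nominal", "values": list(a.values)}
        else:
            attrs[a.name] = {"kind": "ordered", "low": a.low, "high": a.high}
    return {"outcome": outcome, "attributes": attrs}


def read_schema(path) -> tuple[list[AttributeSchema], str]:
    with open(path) as fh:
        return schema_from_dict(yaml.safe_load(fh))


def write_schema(schema: Sequence[AttributeSchema], outcome: str, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(schema_to_dict(schema, outcome), fh, sort_keys=False)


def read_dataset(path, schema_path_or_config) -> CohortDataset:
    """Load a typed cohort from a delimited file plus a schema config.

    The delimiter is inferred from the extension (``.tsv`` -> tab).
    Missing values and out-of-domain values are rejected with row/column
    coordinates (via :class:`CohortDataset` validation).
    """
    if isinstance(schema_path_or_config, (str, Path)):
        schema, outcome_col = read_schema(schema_path_or_config)
    else:
        schema, outcome_col = schema_from_dict(schema_path_or_config)
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, index_col=0)
    frame.index.name = None
    if outcome_col not in frame.columns:
        raise SchemaError(f"outcome column {outcome_col!r} missing from {path}")
    outcome = frame.pop(outcome_col)
    return CohortDataset(schema, frame, outcome)


def write_dataset(dataset: CohortDataset, path, outcome_col: str = "outcome") -> None:
    frame = dataset.frame.copy()
    frame[outcome_col] = dataset.outcome
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    frame.to_csv(path, sep=sep, index_label="id")


def rules_to_json(classifier: Classifier) -> list[dict]:
    out = []
    for rule in classifier.rules:
        entry = {"id": rule.id, "rule": format_rule(rule),
                 "consequence": rule.consequence}
        if rule.stats is not None:
            s = rule.stats
            entry["stats"] = {
                "covering": s.covering, "error": s.error,
                "precision": s.precision,
            }
        out.append(entry)
    return out


def write_rules(classifier: Classifier, path) -> None:
    with open(path, "w") as fh:
        json.dump(rules_to_json(classifier), fh, indent=2)
        fh.write("\n")


def read_rules(path, schema: Sequence[AttributeSchema]) -> Classifier:
    """Load a rule file (JSON objects or plain grammar lines)."""
    text = Path(path).read_text()
    rules: list[Rule] = []
    stripped = text.strip()
    if not stripped:
        return Classifier([], list(schema))
    if stripped.startswith("["):
        for entry in json.loads(stripped):
            rule = parse_rule(entry["rule"], schema, entry.get("id", "r"))
            stats = entry.get("stats")
            if stats:
                rule = Rule(rule.id, rule.conditions, rule.consequence,
                            RuleStats(stats["covering"], stats["error"],
                                      stats["precision"]))
            rules.append(rule)
    else:
        for i, line in enumerate(stripped.splitlines()):
            line = line.strip()
            if line and not line.startswith("#"):
                rules.append(parse_rule(line, schema, f"r{i + 1}"))
    return Classifier(rules, list(schema))
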