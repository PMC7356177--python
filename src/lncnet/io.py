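"""Readers and writers for every external table the pipeline touches.

Dialect: UTF-8, tab-separated, exactly one header row; lines starting with
``#`` are comments and are ignored everywhere. Identifiers are opaque,
case-sensitive strings.

Files
-----
expression matrix   first column = feature id, remaining columns = samples
groups table        columns (sample_id, group) with group in {case, control}
classes table       columns (feature_id, class) with class in {coding, lncRNA}
edge list           columns (protein_a, protein_b, experimental_score);
                    STRING exports both directions, so reciprocal rows are
                    collapsed to one undirected edge keeping the max score
regulatory pairs    two-column id pairs; an optional third "evidence" column
                    is checked against an accepted-label set
GMT                 standard: set name, description, then members
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .data import (
    FEATURE_CLASSES,
    GROUPS,
    ExpressionMatrix,
    GeneSetCollection,
    RegulatoryAnnotation,
)
from .errors import FormatError

log = logging.getLogger(__name__)

_READ_KW = dict(sep="\t", comment="#", dtype=str, keep_default_na=False)


def _read_table(path: str | Path, n_cols_min: int) -> pd.DataFrame:
    df = pd.read_csv(path, **_READ_KW)
    if df.shape[1] < n_cols_min:
        raise FormatError(f"{path}: expected >= {n_cols_min} columns, "
                          f"found {df.shape[1]}")
    return df


def _two_column_map(path: str | Path, allowed: tuple[str, ...],
                    kind: str) -> dict[str, str]:
    df = _read_table(path, 2)
    out: dict[str, str] = {}
    for _, row in df.iterrows():
        key, value = row.iloc[0], row.iloc[1]
        if key in out:
            raise FormatError(f"{path}: duplicate {kind} {key!r}")
        if value not in allowed:
            raise FormatError(
                f"{path}: {kind} {key!r} has unknown label {value!r} "
                f"(expected one of {allowed})")
        out[key] = value
    return out


def read_expression(matrix_path: str | Path, groups_path: str | Path,
                    classes_path: str | Path) -> ExpressionMatrix:
    """Read and validate the three expression-matrix tables.

    Raises :class:`~lncnet.errors.FormatError` naming the offending
    identifier for duplicate ids, unlabeled samples/features or
    non-numeric cells.
    """
    raw = pd.read_csv(matrix_path, sep="\t", comment="#", index_col=0,
                      float_precision="round_trip")
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise FormatError(f"{matrix_path}: duplicate feature id {dup!r}")
    for col in raw.columns:
        if not pd.api.types.is_numeric_dtype(raw[col]):
            bad = raw[col][pd.to_numeric(raw[col], errors="coerce").isna()]
            raise FormatError(
                f"{matrix_path}: non-numeric cell in column {col!r}, "
                f"row {bad.index[0]!r}: {bad.iloc[0]!r}")
    group_of = _two_column_map(groups_path, GROUPS, "sample")
    class_of = _two_column_map(classes_path, FEATURE_CLASSES, "feature")
    values = raw.astype(float)
    values.index.name = None
    values.columns.name = None
    return ExpressionMatrix(values=values, group_of=group_of,
                            class_of=class_of)


def write_expression(matrix: ExpressionMatrix, matrix_path: str | Path,
                     groups_path: str | Path, classes_path: str | Path) -> None:
    # %.17g round-trips every float64 exactly
    matrix.values.to_csv(matrix_path, sep="\t", index_label="feature_id",
                         float_format="%.17g")
    pd.DataFrame(
        {"sample_id": matrix.sample_ids,
         "group": [matrix.group_of[s] for s in matrix.sample_ids]}
    ).to_csv(groups_path, sep="\t", index=False)
    pd.DataFrame(
        {"feature_id": matrix.feature_ids,
         "class": [matrix.class_of[f] for f in matrix.feature_ids]}
    ).to_csv(classes_path, sep="\t", index=False)


def read_edge_list(path: str | Path, min_score: float = 0.4) -> nx.Graph:
    """Read a STRING-style edge list into an undirected simple graph.

    Self-loops are dropped; duplicate and reciprocal rows collapse to one
    edge keeping the maximum score; edges whose collapsed score is below
    ``min_score`` are excluded. Nodes are the endpoints of retained edges.
    """
    best: dict[tuple[str, str], float] = {}
    with open(path, encoding="utf-8") as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, "
                                  f"found {len(parts)}")
            a, b, raw_score = parts[0], parts[1], parts[2]
            try:
                score = float(raw_score)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric score {raw_score!r}") from exc
            if not 0.0 <= score <= 1.0:
                raise FormatError(
                    f"{path}:{lineno}: score {score} outside [0, 1]")
            if a == b:
                continue
            key = (a, b) if a < b else (b, a)
            best[key] = max(best.get(key, 0.0), score)
    graph = nx.Graph()
    for (a, b), score in best.items():
        if score >= min_score:
            graph.add_edge(a, b, score=score)
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    rows = sorted(
        (min(a, b), max(a, b), data.get("score", 1.0))
        for a, b, data in graph.edges(data=True)
    )
    pd.DataFrame(rows, columns=["protein_a", "protein_b", "experimental_score"]
                 ).to_csv(path, sep="\t", index=False)


def _read_pairs(path: str | Path,
                accepted_evidence: tuple[str, ...] | None) -> set[tuple[str, str]]:
    df = _read_table(path, 2)
    pairs: set[tuple[str, str]] = set()
    dropped = 0
    for _, row in df.iterrows():
        if accepted_evidence is not None and df.shape[1] >= 3:
            if row.iloc[2] not in accepted_evidence:
                dropped += 1
                continue
        pairs.add((row.iloc[0], row.iloc[1]))
    if dropped:
        log.info("%s: dropped %d rows with unaccepted evidence labels",
                 path, dropped)
    return pairs


def read_regulatory(lnc_mirna_path: str | Path, lnc_gene_path: str | Path,
                    mirna_gene_path: str | Path,
                    accepted_evidence: tuple[str, ...] | None = None
                    ) -> RegulatoryAnnotation:
    """Read the three regulatory pair tables into one annotation object.

    ``accepted_evidence`` restricts rows by their optional third column
    (rows with other labels are dropped and the count logged); ``None``
    accepts every row.
    """
    return RegulatoryAnnotation(
        lnc_to_mirna=frozenset(_read_pairs(lnc_mirna_path, accepted_evidence)),
        lnc_to_gene=frozenset(_read_pairs(lnc_gene_path, accepted_evidence)),
        mirna_to_gene=frozenset(_read_pairs(mirna_gene_path, accepted_evidence)),
    )


def write_pairs(pairs: set[tuple[str, str]], path: str | Path,
                columns: tuple[str, str]) -> None:
    pd.DataFrame(sorted(pairs), columns=list(columns)
                 ).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path,
             universe: set[str] | None = None) -> GeneSetCollection:
    """Read a GMT gene-set file.

    Each non-comment line must have >= 3 tab-separated fields: name,
    description, members. The universe defaults to the union of all
    members when not supplied.
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected >= 3 (name, description, members...)")
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(fields[2:])
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    return GeneSetCollection(sets=sets, universe=frozenset(universe))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\tna\t{members}\n")
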