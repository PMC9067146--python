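"""Readers and writers for the plain-text formats shared by all stages.

Matrices travel as TSV with a leading ``#layer=`` comment line, a
``feature_id`` column and one column per sample; sample metadata as TSV
indexed by ``sample_id``; gene sets as GMT (description field encodes
``level|module``); interactions as SIF-style three-column tables; networks
as GraphML.  Readers fail loudly with the offending file and line rather
than silently coercing.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import networkx as nx
import pandas as pd

from .containers import GeneSet, GeneSetCollection, OmicsMatrix, SchemaError

FLOAT_FMT = "%.10g"  # fixed format keeps re-runs byte-identical


def write_matrix(matrix: OmicsMatrix, matrix_path, metadata_path) -> None:
    with open(matrix_path, "w") as fh:
        fh.write(f"#layer={matrix.layer}\n")
        matrix.values.rename_axis("feature_id").to_csv(fh, sep="\t", float_format=FLOAT_FMT)
    matrix.metadata.rename_axis("sample_id").to_csv(metadata_path, sep="\t")


def read_matrix(matrix_path, metadata_path) -> OmicsMatrix:
    matrix_path = Path(matrix_path)
    with open(matrix_path) as fh:
        first = fh.readline()
        if not first.startswith("#layer="):
            raise SchemaError(f"{matrix_path}:1: expected '#layer=' header line")
        layer = first.strip().split("=", 1)[1]
        body = fh.read()
    try:
        values = pd.read_csv(_io.StringIO(body), sep="\t", index_col="feature_id")
    except (ValueError, KeyError) as exc:
        raise SchemaError(f"{matrix_path}: malformed matrix table: {exc}") from exc
    non_numeric = values.columns[
        [not pd.api.types.is_numeric_dtype(values[c]) for c in values.columns]
    ]
    if len(non_numeric):
        raise SchemaError(f"{matrix_path}: non-numeric sample columns {list(non_numeric)}")
    try:
        metadata = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
    except (ValueError, KeyError) as exc:
        raise SchemaError(f"{metadata_path}: malformed metadata table: {exc}") from exc
    return OmicsMatrix(values, metadata, layer)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term in collection:
            members = "\t".join(sorted(term.members))
            fh.write(f"{term.term_id}\t{term.level}|{term.module}|{term.name}\t{members}\n")


def read_gmt(path) -> GeneSetCollection:
    path = Path(path)
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(f"{path}:{lineno}: GMT line needs id, description, members")
            term_id, desc = fields[0], fields[1]
            parts = desc.split("|", 2)
            if len(parts) == 3:
                level_s, module, name = parts
            else:
                level_s, module, name = "2", "", desc
            try:
                level = int(level_s)
            except ValueError:
                raise SchemaError(
                    f"{path}:{lineno}: description must start with an integer level"
                ) from None
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise SchemaError(f"{path}:{lineno}: term {term_id} has no members")
            coll.add(GeneSet(term_id, name, level, module, members))
    return coll


def write_sif(edges: pd.DataFrame, path) -> None:
    edges[["source", "interaction", "target"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_sif(path) -> pd.DataFrame:
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise SchemaError(
                    f"{path}:{lineno}: SIF line needs source, interaction, target"
                )
            rows.append(dict(zip(("source", "interaction", "target"), fields)))
    return pd.DataFrame(rows, columns=["source", "interaction", "target"])


def read_node_kinds(path) -> dict:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("node_id", "kind"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    return dict(zip(df["node_id"], df["kind"]))


def write_node_kinds(node_kinds: dict, path) -> None:
    pd.DataFrame(
        {"node_id": list(node_kinds), "kind": list(node_kinds.values())}
    ).to_csv(path, sep="\t", index=False)


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def write_stats(stats: pd.DataFrame, path) -> None:
    stats.rename_axis("feature_id").to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_stats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")
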