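"""Readers and writers for the tabular and graph formats the pipeline touches.

All gene identifiers are canonicalized by uppercasing and stripping
whitespace; no alias resolution is attempted.  STRING-style integer
confidence scores (0-1000) are detected automatically and rescaled to [0, 1].
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx

__all__ = [
    "TableSchema",
    "EdgeRecord",
    "GeneSet",
    "SchemaError",
    "canonical_gene",
    "read_table",
    "read_edge_list",
    "read_gmt",
    "write_gmt",
    "write_graph",
    "read_graph",
    "write_gene_list",
    "read_gene_list",
]

ValueKind = Literal["text", "number", "integer", "probability"]


class SchemaError(ValueError):
    """A table does not conform to its declared schema."""


def canonical_gene(symbol: str) -> str:
    """Canonical form of a gene symbol: uppercased, surrounding whitespace stripped."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class TableSchema:
    """Declarative description of a delimited table.

    ``required_columns`` maps column names to a value kind used for parsing
    and validation: ``text``, ``number``, ``integer`` or ``probability``
    (a number constrained to [0, 1]).
    """

    name: str
    required_columns: Sequence[tuple[str, ValueKind]]
    delimiter: str = "\t"

    def __post_init__(self) -> None:
        if not self.required_columns:
            raise ValueError(f"schema {self.name!r}: required_columns must be non-empty")
        names = [c for c, _ in self.required_columns]
        if len(set(names)) != len(names):
            raise ValueError(f"schema {self.name!r}: duplicate column names")


@dataclass(frozen=True)
class EdgeRecord:
    """One undirected interaction with a confidence on [0, 1]."""

    node_a: str
    node_b: str
    confidence: float


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (a GMT line, a pathway, a GO/KEGG term)."""

    id: str
    name: str
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.id!r} is empty")


def _parse_cell(value: str, kind: ValueKind, column: str, row_number: int):
    try:
        if kind == "text":
            return value
        if kind == "integer":
            return int(value)
        parsed = float(value)
    except ValueError:
        raise SchemaError(
            f"row {row_number}: cannot parse {value!r} in column {column!r} as {kind}"
        ) from None
    if kind == "probability" and not 0.0 <= parsed <= 1.0:
        raise SchemaError(
            f"row {row_number}: column {column!r} value {parsed} outside [0, 1]"
        )
    return parsed


def read_table(path: str | Path, schema: TableSchema) -> list[dict]:
    """Read a delimited table, validating it against *schema*.

    Returns one dict per row (required columns parsed per their declared
    kind, extra columns kept as text).  Row order is preserved.
    """
    path = Path(path)
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle, delimiter=schema.delimiter)
        header = reader.fieldnames
        if header is None:
            raise SchemaError(f"{path}: empty file, header row required")
        missing = [c for c, _ in schema.required_columns if c not in header]
        if missing:
            raise SchemaError(
                f"{path}: missing required column(s) {', '.join(repr(m) for m in missing)}"
            )
        rows: list[dict] = []
        for row_number, row in enumerate(reader, start=2):
            parsed = dict(row)
            for column, kind in schema.required_columns:
                parsed[column] = _parse_cell(row[column], kind, column, row_number)
            rows.append(parsed)
    return rows


def read_edge_list(
    path: str | Path,
    score_scale: Literal["auto", "unit", "thousand"] = "auto",
    drop_self_loops: bool = True,
    delimiter: str = "\t",
) -> list[EdgeRecord]:
    """Read a 3-column (node, node, score) edge list.

    Scores are brought onto [0, 1]: with ``score_scale="auto"`` any score
    above 1 flags a 0-1000 (STRING-style) file and every score is divided by
    1000.  Duplicate undirected edges are collapsed keeping the maximum
    confidence.  Self-loops are dropped with a warning by default.
    """
    path = Path(path)
    raw: list[tuple[str, str, float]] = []
    with path.open(newline="") as handle:
        reader = csv.reader(handle, delimiter=delimiter)
        for line_number, parts in enumerate(reader, start=1):
            if not parts or (len(parts) == 1 and not parts[0].strip()):
                continue
            if len(parts) < 3:
                raise SchemaError(f"{path}:{line_number}: expected 3 columns, got {len(parts)}")
            a, b = canonical_gene(parts[0]), canonical_gene(parts[1])
            try:
                score = float(parts[2])
            except ValueError:
                raise SchemaError(
                    f"{path}:{line_number}: cannot parse score {parts[2]!r}"
                ) from None
            if score < 0:
                raise SchemaError(f"{path}:{line_number}: negative score {score}")
            if score > 1000:
                raise SchemaError(f"{path}:{line_number}: score {score} exceeds 1000")
            raw.append((a, b, score))

    if score_scale == "auto":
        scale = 1000.0 if any(s > 1 for _, _, s in raw) else 1.0
    elif score_scale == "thousand":
        scale = 1000.0
    else:
        scale = 1.0

    best: dict[frozenset[str], float] = {}
    order: list[frozenset[str]] = []
    for a, b, score in raw:
        confidence = score / scale
        if confidence > 1.0:
            raise SchemaError(f"score {score} is not on the declared {score_scale!r} scale")
        if a == b:
            if drop_self_loops:
                warnings.warn(f"dropping self-loop on {a!r}", stacklevel=2)
                continue
            raise SchemaError(f"self-loop on {a!r}")
        key = frozenset((a, b))
        if key not in best:
            order.append(key)
            best[key] = confidence
        else:
            best[key] = max(best[key], confidence)

    records = []
    for key in order:
        a, b = sorted(key)
        records.append(EdgeRecord(a, b, best[key]))
    return records


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT gene-set collection: name, description, then gene symbols."""
    path = Path(path)
    sets: list[GeneSet] = []
    for line_number, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise SchemaError(
                f"{path}:{line_number}: GMT line needs >= 3 tab-separated fields"
            )
        genes = frozenset(canonical_gene(g) for g in fields[2:] if g.strip())
        if not genes:
            raise SchemaError(f"{path}:{line_number}: gene set {fields[0]!r} is empty")
        sets.append(GeneSet(id=fields[0], name=fields[1], genes=genes))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    lines = []
    for gs in sets:
        lines.append("\t".join([gs.id, gs.name, *sorted(gs.genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(set(genes))) + "\n")


def read_gene_list(path: str | Path) -> set[str]:
    return {
        canonical_gene(line)
        for line in Path(path).read_text().splitlines()
        if line.strip()
    }


def write_graph(
    network: nx.Graph,
    fmt: Literal["graphml", "node_edge_tables"],
    path: str | Path,
) -> None:
    """Write a confidence-weighted graph as GraphML or Cytoscape-style tables.

    ``node_edge_tables`` writes ``<path>.nodes.tsv`` and ``<path>.edges.tsv``.
    Round-tripping through :func:`read_graph` recovers the node set, edge set
    and confidences to 6 decimals.
    """
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(network, path)
        return
    if fmt != "node_edge_tables":
        raise ValueError(f"unknown graph format {fmt!r}")
    nodes_path = path.with_suffix(path.suffix + ".nodes.tsv")
    edges_path = path.with_suffix(path.suffix + ".edges.tsv")
    with nodes_path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["node"])
        for node in sorted(network.nodes):
            writer.writerow([node])
    with edges_path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["node_a", "node_b", "confidence"])
        for a, b, data in sorted(network.edges(data=True), key=lambda e: tuple(sorted(e[:2]))):
            a, b = sorted((a, b))
            writer.writerow([a, b, f"{data.get('confidence', 1.0):.6f}"])


def read_graph(
    fmt: Literal["graphml", "node_edge_tables"],
    path: str | Path,
) -> nx.Graph:
    path = Path(path)
    if fmt == "graphml":
        graph = nx.read_graphml(path)
        return nx.relabel_nodes(graph, {n: str(n) for n in graph.nodes})
    nodes_path = path.with_suffix(path.suffix + ".nodes.tsv")
    edges_path = path.with_suffix(path.suffix + ".edges.tsv")
    graph = nx.Graph()
    with nodes_path.open(newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            graph.add_node(row["node"])
    with edges_path.open(newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            graph.add_edge(row["node_a"], row["node_b"], confidence=float(row["confidence"]))
    return graph
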