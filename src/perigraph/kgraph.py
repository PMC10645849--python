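"""Heterogeneous patient / risk-factor knowledge graph.

Each patient record becomes one PATIENT node. Each observed (feature, level)
pair — including level 0 of a binary factor, since shared *absence* of a
risk factor is also similarity — becomes one FEATURE_VALUE node. A typed
edge ``HAS_<FEATURE>`` links a patient to the value node of every risk
factor observed for them; missing values contribute no edge. The graph is
therefore bipartite, and patient similarity is induced purely through
shared FEATURE_VALUE neighbours.

Outcome labels are excluded by default: embedding the target class would
leak labels into an evaluation framed as prediction. ``include_outcome=True``
adds OUTCOME value nodes for fidelity to the label-bearing variant.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import CohortTable

PATIENT = "PATIENT"
FEATURE_VALUE = "FEATURE_VALUE"

_EXPORT_FORMATS = ("graphml", "edgelist-csv", "neo4j-import-csv")


class GraphError(ValueError):
    pass


def patient_node(pid: str) -> str:
    return f"patient:{pid}"


def value_node(feature: str, level) -> str:
    return f"value:{feature}={level}"


@dataclass
class KnowledgeGraph:
    """Thin wrapper over an undirected ``networkx.Graph``.

    Node attributes: ``node_type`` (PATIENT / FEATURE_VALUE), and for value
    nodes ``feature_name`` and ``level``. Edge attribute: ``relation``
    (``HAS_<FEATURE>``). Node insertion order is deterministic — patients in
    table order, then value nodes in feature/level order — and is the row
    order of every embedding matrix computed from the graph.
    """

    nx: nx.Graph

    @property
    def patient_ids(self) -> list[str]:
        return [n[len("patient:"):] for n, d in self.nx.nodes(data=True)
                if d["node_type"] == PATIENT]

    def node_order(self) -> list[str]:
        return list(self.nx.nodes)

    def is_bipartite_typed(self) -> bool:
        for u, v in self.nx.edges:
            if self.nx.nodes[u]["node_type"] == self.nx.nodes[v]["node_type"]:
                return False
        return True


@dataclass(frozen=True)
class GraphStats:
    n_nodes: int
    n_patient_nodes: int
    n_entity_nodes: int
    n_relationships: int

    def __post_init__(self):
        assert self.n_nodes == self.n_patient_nodes + self.n_entity_nodes


def _level_strings(col: pd.Series, kind: str, levels: tuple) -> pd.Series:
    """Map a parsed feature column to discrete level strings (NaN preserved)."""
    if kind == "binary":
        return col.map(lambda v: v if pd.isna(v) else str(int(v)))
    if kind == "categorical":
        return col.map(lambda v: v if pd.isna(v) else str(levels[int(v)]))
    # continuous: quartile bins over observed values
    observed = col.dropna()
    if observed.nunique() < 2:
        return col.map(lambda v: v if pd.isna(v) else "q1")
    binned = pd.qcut(col, q=4, labels=["q1", "q2", "q3", "q4"], duplicates="drop")
    return binned.astype(object)


def build_graph(table: CohortTable, include_outcome: bool = False) -> KnowledgeGraph:
    """Construct the bipartite knowledge graph of a cohort.

    Deterministic: no randomness, node order fixed by table order. All-missing
    feature columns are skipped with a warning.
    """
    if table.n == 0:
        raise GraphError("empty cohort table")
    g = nx.Graph()
    for pid in table.patient_id:
        g.add_node(patient_node(pid), node_type=PATIENT, patient_id=str(pid))

    for spec in table.schema.features:
        col = table.features[spec.name]
        if col.isna().all():
            warnings.warn(f"feature {spec.name!r} is entirely missing; skipped",
                          stacklevel=2)
            continue
        levels = _level_strings(col, spec.kind, spec.levels)
        relation = f"HAS_{spec.name.upper()}"
        for pid, lev in zip(table.patient_id, levels):
            if pd.isna(lev):
                continue
            vn = value_node(spec.name, lev)
            if vn not in g:
                g.add_node(vn, node_type=FEATURE_VALUE,
                           feature_name=spec.name, level=str(lev))
            g.add_edge(patient_node(pid), vn, relation=relation)

    if include_outcome:
        for outcome in table.labels.columns:
            relation = f"HAS_OUTCOME_{outcome.upper()}"
            for pid, lab in zip(table.patient_id, table.labels[outcome]):
                vn = value_node(f"outcome_{outcome}", int(lab))
                if vn not in g:
                    g.add_node(vn, node_type=FEATURE_VALUE,
                               feature_name=f"outcome_{outcome}", level=str(int(lab)))
                g.add_edge(patient_node(pid), vn, relation=relation)
    return KnowledgeGraph(g)


def graph_stats(g: KnowledgeGraph) -> GraphStats:
    types = [d["node_type"] for _, d in g.nx.nodes(data=True)]
    n_pat = sum(t == PATIENT for t in types)
    return GraphStats(
        n_nodes=g.nx.number_of_nodes(),
        n_patient_nodes=n_pat,
        n_entity_nodes=g.nx.number_of_nodes() - n_pat,
        n_relationships=g.nx.number_of_edges(),
    )


def adjacency_matrix(g: KnowledgeGraph, order: list[str] | None = None):
    """Undirected, unweighted sparse adjacency in node order (no self-loops)."""
    return nx.to_scipy_sparse_array(g.nx, nodelist=order or g.node_order(),
                                    weight=None, format="csr", dtype=float)


def export_graph(g: KnowledgeGraph, out_dir, fmt: str) -> list[Path]:
    """Write the graph to ``out_dir``; returns the files created.

    graphml and edgelist-csv round-trip losslessly through
    :func:`import_graph`; neo4j-import-csv emits a ``nodes.csv`` /
    ``relationships.csv`` pair in the bulk-import header dialect.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt == "graphml":
        path = out_dir / "graph.graphml"
        nx.write_graphml(g.nx, path)
        return [path]
    if fmt == "edgelist-csv":
        npath, epath = out_dir / "nodes.csv", out_dir / "edges.csv"
        with open(npath, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["node_id", "node_type", "feature_name", "level"])
            for n, d in g.nx.nodes(data=True):
                w.writerow([n, d["node_type"], d.get("feature_name", ""), d.get("level", "")])
        with open(epath, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["src", "dst", "relation"])
            for u, v, d in g.nx.edges(data=True):
                w.writerow([u, v, d["relation"]])
        return [npath, epath]
    if fmt == "neo4j-import-csv":
        npath, epath = out_dir / "nodes.csv", out_dir / "relationships.csv"
        with open(npath, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["nodeId:ID", ":LABEL", "feature_name", "level"])
            for n, d in g.nx.nodes(data=True):
                w.writerow([n, d["node_type"], d.get("feature_name", ""), d.get("level", "")])
        with open(epath, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow([":START_ID", ":END_ID", ":TYPE"])
            for u, v, d in g.nx.edges(data=True):
                w.writerow([u, v, d["relation"]])
        return [npath, epath]
    raise GraphError(f"unknown export format {fmt!r}; options: {_EXPORT_FORMATS}")


def import_graph(path_or_dir, fmt: str) -> KnowledgeGraph:
    """Inverse of :func:`export_graph` for graphml and edgelist-csv."""
    p = Path(path_or_dir)
    if fmt == "graphml":
        if p.is_dir():
            p = p / "graph.graphml"
        g = nx.read_graphml(p)
        g = nx.relabel_nodes(nx.Graph(g), str)
        return KnowledgeGraph(g)
    if fmt == "edgelist-csv":
        g = nx.Graph()
        with open(p / "nodes.csv", newline="") as fh:
            for row in csv.DictReader(fh):
                attrs = {"node_type": row["node_type"]}
                if row["node_type"] == FEATURE_VALUE:
                    attrs.update(feature_name=row["feature_name"], level=row["level"])
                else:
                    attrs["patient_id"] = row["node_id"][len("patient:"):]
                g.add_node(row["node_id"], **attrs)
        with open(p / "edges.csv", newline="") as fh:
            for row in csv.DictReader(fh):
                g.add_edge(row["src"], row["dst"], relation=row["relation"])
        return KnowledgeGraph(g)
    raise GraphError(f"cannot import format {fmt!r}")


def shared_risk_factors(g: KnowledgeGraph, patient_ids: list[str]) -> list[tuple[str, int]]:
    """Rank FEATURE_VALUE nodes by how many of the listed patients carry them.

    Used to explain a set of flagged outliers by their common risk factors:
    value nodes shared by all listed patients come first, ties broken
    lexicographically by node id. Returns (node_id, share_count) pairs for
    every value node touched by at least one listed patient.
    """
    counts: dict[str, int] = {}
    for pid in patient_ids:
        pn = patient_node(pid)
        if pn not in g.nx:
            raise GraphError(f"unknown patient id {pid!r}")
        for nbr in g.nx.neighbors(pn):
            if g.nx.nodes[nbr]["node_type"] == FEATURE_VALUE:
                counts[nbr] = counts.get(nbr, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
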