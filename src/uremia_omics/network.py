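"""Metabolite-protein disease-interactome assembly.

Seeds — elevated metabolites (categories I + II) and differential serum
proteins — are joined through a STITCH-style chemical-protein association
table. The resulting undirected subnetwork keeps every seed (isolated
seeds are flagged) and, optionally, all direct (one-hop) neighbors, with
edges restricted to retained nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd


@dataclass(frozen=True)
class AssociationEdge:
    """One metabolite-protein association with a confidence score in (0, 1]."""

    metabolite: str
    protein: str
    score: float

    def __post_init__(self) -> None:
        if not self.metabolite or not self.protein:
            raise ValueError("edge endpoints must be nonempty ids")
        if self.metabolite == self.protein:
            raise ValueError("self loops are not allowed")
        if not 0 < self.score <= 1:
            raise ValueError("combined score must lie in (0, 1]")


def load_edges(path: str | Path, score_min: float = 0.4) -> list[AssociationEdge]:
    """Read a STITCH-dialect TSV (columns ``chemical``, ``protein``,
    ``combined_score``), keeping edges with score >= score_min and
    collapsing duplicate pairs to their maximum score.

    Scores on STITCH's integer 0-1000 scale are rescaled to (0, 1].
    """
    df = pd.read_csv(path, sep="\t", dtype={"chemical": str, "protein": str})
    required = {"chemical", "protein", "combined_score"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    best: dict[tuple[str, str], float] = {}
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            score = float(row.combined_score)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: bad combined_score") from exc
        if score > 1:  # STITCH integer scale
            score = score / 1000.0
        pair = (str(row.chemical), str(row.protein))
        if not pair[0] or not pair[1]:
            raise ValueError(f"{path}:{lineno}: empty identifier")
        best[pair] = max(best.get(pair, 0.0), score)
    return [
        AssociationEdge(m, p, s)
        for (m, p), s in sorted(best.items())
        if s >= score_min
    ]


def write_edges(edges: Iterable[AssociationEdge], path: str | Path) -> None:
    pd.DataFrame(
        [(e.metabolite, e.protein, e.score) for e in edges],
        columns=["chemical", "protein", "combined_score"],
    ).to_csv(path, sep="\t", index=False)


def build_disease_network(
    metabolite_seeds: Iterable[str],
    protein_seeds: Iterable[str] | Mapping[str, str],
    edges: Iterable[AssociationEdge],
    include_neighbors: bool = True,
    metabolite_categories: Mapping[str, str] | None = None,
    protein_directions: Mapping[str, str] | None = None,
    synonym_map: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Assemble the disease interactome around the seed sets.

    Metabolite seeds default to status ``seed-up`` (they are the elevated
    set); protein seeds take their direction from ``protein_directions``
    (``up``/``down``, default up). Seeds are retained even when no edge
    touches them. With ``include_neighbors``, every node one hop from a
    seed joins with status ``neighbor``; edges are then restricted to
    retained nodes. ``synonym_map`` renames seed ids into the edge-table
    vocabulary by exact lookup before matching.

    Node attributes: ``kind`` (metabolite/protein), ``status``
    (seed-up/seed-down/neighbor), ``category`` for metabolites when
    supplied; edge attribute ``score``.
    """
    syn = dict(synonym_map or {})
    met_seeds = [syn.get(m, m) for m in metabolite_seeds]
    if isinstance(protein_seeds, Mapping):
        protein_directions = dict(protein_seeds)
        prot_seeds = [syn.get(p, p) for p in protein_seeds]
    else:
        prot_seeds = [syn.get(p, p) for p in protein_seeds]
    directions = dict(protein_directions or {})
    categories = dict(metabolite_categories or {})

    full = nx.Graph()
    for e in edges:
        full.add_node(e.metabolite, kind="metabolite")
        full.add_node(e.protein, kind="protein")
        prev = full.get_edge_data(e.metabolite, e.protein)
        if prev is None or prev["score"] < e.score:
            full.add_edge(e.metabolite, e.protein, score=e.score)

    g = nx.Graph()
    for m in met_seeds:
        g.add_node(m, kind="metabolite", status="seed-up")
        cat = categories.get(m)
        if cat is not None:
            g.nodes[m]["category"] = cat
    for p in prot_seeds:
        status = "seed-down" if directions.get(p, "up") == "down" else "seed-up"
        g.add_node(p, kind="protein", status=status)

    seeds = set(g.nodes)
    if include_neighbors:
        for s in seeds & set(full.nodes):
            for nb in full.neighbors(s):
                if nb not in g:
                    g.add_node(nb, kind=full.nodes[nb]["kind"], status="neighbor")
    for u, v, data in full.edges(data=True):
        if u in g and v in g:
            g.add_edge(u, v, score=data["score"])
    return g


def export_graph(net: nx.Graph, path: str | Path, fmt: str = "sif") -> None:
    """Write the network as SIF, GraphML or an edge TSV.

    SIF: one ``source  association  target`` line per edge plus a bare
    line per isolated node, so the node set round-trips exactly.
    """
    path = Path(path)
    if fmt == "sif":
        with open(path, "w") as fh:
            for u, v in sorted(map(tuple, map(sorted, net.edges()))):
                fh.write(f"{u}\tassociation\t{v}\n")
            for node in sorted(net.nodes):
                if net.degree(node) == 0:
                    fh.write(f"{node}\n")
    elif fmt == "graphml":
        nx.write_graphml(net, path)
    elif fmt == "tsv":
        rows = [
            {"source": u, "target": v, "score": d.get("score", "")}
            for u, v, d in net.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "score"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown export format {fmt!r}; use sif, graphml or tsv")


def read_sif(path: str | Path) -> nx.Graph:
    """Parse a SIF file back into a graph (nodes and edges only)."""
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 1 and parts[0]:
                g.add_node(parts[0])
            elif len(parts) == 3:
                g.add_edge(parts[0], parts[2])
            elif any(p for p in parts):
                raise ValueError(f"malformed SIF line: {line!r}")
    return g
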