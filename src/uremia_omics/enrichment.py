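"""Hypergeometric over-representation analysis of metabolite sets.

Tests whether a query set (typically the elevated metabolites, categories
I + II) overlaps a pathway/disease set more than expected by chance, given
a background universe: upper-tail hypergeometric p = P(X >= k) with
X ~ Hypergeom(N, K, n) for overlap k, pathway size K (within the
universe), query size n, universe size N. Benjamini-Hochberg q-values are
computed across pathways.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

from .differential_stats import adjust_fdr_bh


@dataclass
class PathwaySet:
    name: str
    members: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise ValueError(f"pathway {self.name!r} has no members")


@dataclass
class EnrichmentResult:
    pathway: str
    k_overlap: int
    K_pathway: int
    n_query: int
    N_universe: int
    p: float
    q: float | None = None


def read_gmt(path: str | Path, source: str = "") -> list[PathwaySet]:
    """Read pathway sets from a GMT file (name, description, members...)."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, "
                                 "description and >= 1 member")
            name, desc = parts[0], parts[1]
            members = [m for m in parts[2:] if m]
            sets.append(PathwaySet(name=name, members=frozenset(members),
                                   source=source or desc))
    return sets


def write_gmt(sets: dict[str, list[str]] | list[PathwaySet], path: str | Path,
              description: str = "synthetic") -> None:
    if isinstance(sets, dict):
        sets = [PathwaySet(name=k, members=frozenset(v), source=description)
                for k, v in sets.items()]
    with open(path, "w") as fh:
        for ps in sets:
            fh.write("\t".join([ps.name, ps.source or description,
                                *sorted(ps.members)]) + "\n")


def overrepresentation_test(
    query: set[str], pathway: PathwaySet, universe: set[str]
) -> EnrichmentResult:
    """Upper-tail hypergeometric test of query/pathway overlap.

    The pathway is intersected with the universe first; the query must be
    a subset of the universe.
    """
    query = set(query)
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be nonempty")
    if not query:
        raise ValueError("query must be nonempty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    members = set(pathway.members) & universe
    k = len(query & members)
    K = len(members)
    n = len(query)
    N = len(universe)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
    return EnrichmentResult(pathway=pathway.name, k_overlap=k, K_pathway=K,
                            n_query=n, N_universe=N, p=min(p, 1.0))


def enrich_all(
    query: set[str], pathways: list[PathwaySet], universe: set[str]
) -> pd.DataFrame:
    """ORA over all pathways with BH q-values, sorted by ascending p
    (ties broken by pathway name)."""
    if not pathways:
        raise ValueError("need at least one pathway set")
    results = [overrepresentation_test(query, ps, universe) for ps in pathways]
    df = pd.DataFrame(
        {
            "pathway": [r.pathway for r in results],
            "k_overlap": [r.k_overlap for r in results],
            "K_pathway": [r.K_pathway for r in results],
            "n_query": [r.n_query for r in results],
            "N_universe": [r.N_universe for r in results],
            "p": [r.p for r in results],
        }
    )
    df["q"] = adjust_fdr_bh(df["p"].to_numpy())
    return df.sort_values(["p", "pathway"], kind="stable").reset_index(drop=True)
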