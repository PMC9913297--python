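"""Target prioritisation and interaction-network structure.

Combines two evidence streams into one prioritised target set:

* source 1 — genes from the transcriptome of patient-derived cancer
  stem-like cells (a plain gene list), and
* source 2 — genes significantly increased in 3D spheroids versus 2D
  culture from the differential-expression stage.

Network structure (degree within the target universe, mutually-interacting
cores) is computed from a protein-association edge list; the heavy lifting
is delegated to networkx.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd


class Evidence(enum.Enum):
    """Channel from which a protein-association edge was derived."""

    EXPERIMENTAL = "experimental"
    CURATED = "curated"
    COEXPRESSION = "coexpression"
    TEXTMINING = "textmining"


@dataclass(frozen=True)
class NetworkEdge:
    """Undirected protein-association edge; self-loops are rejected."""

    a: str
    b: str
    evidence: Evidence

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", self.a.strip().upper())
        object.__setattr__(self, "b", self.b.strip().upper())
        if self.a == self.b:
            raise ValueError(f"self-loop on {self.a} rejected")

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.a, self.b)))  # type: ignore[return-value]


@dataclass
class TargetGene:
    """A prioritised gene with its evidence sources (1, 2 or both)."""

    symbol: str
    sources: set[int] = field(default_factory=set)
    has_drug: bool = False

    def __post_init__(self) -> None:
        self.symbol = self.symbol.strip().upper()
        if not self.sources or not self.sources <= {1, 2}:
            raise ValueError(f"sources for {self.symbol} must be a non-empty subset of {{1, 2}}")


def merge_target_sources(
    de_up: Iterable[str], escsc_list: Iterable[str]
) -> list[TargetGene]:
    """Union the DE-increased genes (source 2) with the patient-derived
    stem-cell list (source 1), case-insensitively deduplicated.

    Returns targets sorted by symbol.
    """
    up = {g.strip().upper() for g in de_up if g.strip()}
    stem = {g.strip().upper() for g in escsc_list if g.strip()}
    if not up and not stem:
        raise ValueError("both gene lists are empty")
    out = []
    for sym in sorted(up | stem):
        sources = set()
        if sym in stem:
            sources.add(1)
        if sym in up:
            sources.add(2)
        out.append(TargetGene(symbol=sym, sources=sources))
    return out


def _graph(edges: Iterable[NetworkEdge], universe: Iterable[str] | None = None) -> nx.Graph:
    g = nx.Graph()
    if universe is not None:
        g.add_nodes_from(s.strip().upper() for s in universe)
    for e in edges:
        if universe is None or (e.a in g and e.b in g):
            g.add_edge(e.a, e.b)
    return g


def target_degree(
    edges: Sequence[NetworkEdge],
    node: str,
    universe: Iterable[str],
    *,
    channels: frozenset[Evidence] | None = None,
) -> int:
    """Distinct neighbours of ``node`` within the target universe.

    Duplicate and reversed edges count once.  ``channels`` restricts which
    evidence channels contribute (default: all four).
    """
    universe = {s.strip().upper() for s in universe}
    if not universe:
        raise ValueError("universe is empty")
    node = node.strip().upper()
    if node not in universe:
        raise ValueError(f"node {node} not in universe")
    if channels is not None:
        edges = [e for e in edges if e.evidence in channels]
    g = _graph(edges, universe)
    return g.degree(node)


def mutually_interacting_core(
    edges: Sequence[NetworkEdge],
    universe: Iterable[str],
    k: int = 2,
    *,
    channels: frozenset[Evidence] | None = None,
) -> list[frozenset[str]]:
    """Maximal cliques of size ≥ k in the universe-induced graph.

    A clique is a set of genes all of whose pairs interact — the strict
    reading of a "mutually interacting" core.  Sorted by size descending,
    then lexicographically.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if channels is not None:
        edges = [e for e in edges if e.evidence in channels]
    g = _graph(edges, {s.strip().upper() for s in universe})
    cliques = [frozenset(c) for c in nx.find_cliques(g) if len(c) >= k]
    return sorted(cliques, key=lambda c: (-len(c), sorted(c)))


def connected_core(
    edges: Sequence[NetworkEdge],
    universe: Iterable[str],
    *,
    channels: frozenset[Evidence] | None = None,
) -> list[frozenset[str]]:
    """Connected components (size ≥ 2) of the universe-induced graph.

    The looser reading of "interacting" genes: connectivity rather than
    pairwise completeness.  Emitted alongside cliques so either statistic
    can be inspected.
    """
    if channels is not None:
        edges = [e for e in edges if e.evidence in channels]
    g = _graph(edges, {s.strip().upper() for s in universe})
    comps = [frozenset(c) for c in nx.connected_components(g) if len(c) >= 2]
    return sorted(comps, key=lambda c: (-len(c), sorted(c)))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.upper())
    return out


def read_edge_list(path: str | Path) -> list[NetworkEdge]:
    """TSV with columns a, b, evidence."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"a", "b", "evidence"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        NetworkEdge(a=r.a, b=r.b, evidence=Evidence(r.evidence)) for r in df.itertuples()
    ]


def targets_frame(
    targets: Sequence[TargetGene], edges: Sequence[NetworkEdge] | None = None
) -> pd.DataFrame:
    """Targets table with symbol, sources, degree and has_drug columns."""
    universe = [t.symbol for t in targets]
    degrees = (
        {t.symbol: target_degree(edges, t.symbol, universe) for t in targets}
        if edges is not None and universe
        else {t.symbol: 0 for t in targets}
    )
    return pd.DataFrame(
        [
            {
                "symbol": t.symbol,
                "sources": ",".join(str(s) for s in sorted(t.sources)),
                "degree": degrees[t.symbol],
                "has_drug": t.has_drug,
            }
            for t in targets
        ]
    )
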