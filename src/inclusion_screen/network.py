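"""Physical-interaction subnetworks of hit genes.

Nodes are hit genes, edges are physical interactions only (genetic
interactions are filtered out during construction), and modules are the
connected components of the induced subgraph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

EDGE_KINDS = ("physical", "genetic")

# BioGRID TAB 3.0 column names used by the dialect reader
_BIOGRID_A = "Official Symbol Interactor A"
_BIOGRID_B = "Official Symbol Interactor B"
_BIOGRID_KIND = "Experimental System Type"


@dataclass(frozen=True)
class InteractionEdge:
    """An undirected gene-gene interaction; (a, b) is stored sorted."""

    gene_a: str
    gene_b: str
    kind: str
    source: str = ""
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.kind not in EDGE_KINDS:
            raise ValueError(f"kind must be one of {EDGE_KINDS}")
        if self.gene_a == self.gene_b:
            raise ValueError("self-loops are not valid edges")
        if self.gene_a > self.gene_b:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def load_edges(path: str | Path, dialect: str = "auto") -> list[InteractionEdge]:
    """Read an interaction edge list from TSV.

    Dialects: ``"biogrid"`` keys on the TAB 3.0 headers (official symbols
    A/B plus experimental system type), ``"plain"`` expects columns
    gene_a, gene_b, kind (plus optional source); ``"auto"`` sniffs the
    header.  Duplicate same-kind pairs collapse into one edge with a
    multiplicity count; self-loops and unknown kinds are dropped with a
    log message.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.empty and frame.shape[1] == 0:
        return []
    if dialect == "auto":
        dialect = "biogrid" if _BIOGRID_A in frame.columns else "plain"
    if dialect == "biogrid":
        cols = (_BIOGRID_A, _BIOGRID_B, _BIOGRID_KIND)
        missing = set(cols) - set(frame.columns)
        if missing:
            raise ValueError(f"BioGRID file missing columns {sorted(missing)}")
        a_col, b_col, kind_col = cols
        source_col = "Publication Source" if "Publication Source" in frame.columns else None
    elif dialect == "plain":
        missing = {"gene_a", "gene_b", "kind"} - set(frame.columns)
        if missing:
            raise ValueError(f"edge file missing columns {sorted(missing)}")
        a_col, b_col, kind_col = "gene_a", "gene_b", "kind"
        source_col = "source" if "source" in frame.columns else None
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    merged: dict[tuple[str, str, str], dict] = {}
    n_self = 0
    for row in frame.itertuples(index=False):
        a = str(row[frame.columns.get_loc(a_col)])
        b = str(row[frame.columns.get_loc(b_col)])
        kind = str(row[frame.columns.get_loc(kind_col)]).strip().lower()
        if a == b:
            n_self += 1
            continue
        if kind not in EDGE_KINDS:
            log.warning("skipping edge %s-%s with unknown kind %r", a, b, kind)
            continue
        key = (min(a, b), max(a, b), kind)
        if key in merged:
            merged[key]["multiplicity"] += 1
        else:
            source = str(row[frame.columns.get_loc(source_col)]) if source_col else ""
            merged[key] = {"source": source, "multiplicity": 1}
    if n_self:
        log.info("dropped %d self-loop rows", n_self)
    return [
        InteractionEdge(a, b, kind, info["source"], info["multiplicity"])
        for (a, b, kind), info in merged.items()
    ]


def write_edges(edges: list[InteractionEdge], path: str | Path) -> None:
    """Plain-dialect TSV writer (round-trips with load_edges)."""
    rows = [
        {
            "gene_a": e.gene_a,
            "gene_b": e.gene_b,
            "kind": e.kind,
            "source": e.source,
        }
        for e in sorted(edges, key=lambda e: (e.gene_a, e.gene_b, e.kind))
        for _ in range(e.multiplicity)
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "kind", "source"]).to_csv(
        path, sep="\t", index=False
    )


@dataclass
class HitNetwork:
    """Induced physical-interaction subgraph over a hit list."""

    graph: nx.Graph
    modules: list[list[str]] = field(default_factory=list)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [tuple(sorted(e)) for e in self.graph.edges]


def build_hit_network(hits: set[str], edges: list[InteractionEdge]) -> HitNetwork:
    """Keep only physical edges with both endpoints in the hit list.

    Genetic edges are discarded entirely; hits without any physical partner
    remain as singleton nodes (and hence singleton modules).
    """
    if not hits:
        raise ValueError("hit list is empty")
    graph = nx.Graph()
    graph.add_nodes_from(sorted(str(h) for h in hits))
    for edge in edges:
        if edge.kind != "physical":
            continue
        if edge.gene_a in graph and edge.gene_b in graph:
            graph.add_edge(
                edge.gene_a, edge.gene_b, multiplicity=edge.multiplicity, source=edge.source
            )
    net = HitNetwork(graph=graph)
    net.modules = find_modules(net)
    return net


def find_modules(net: HitNetwork) -> list[list[str]]:
    """Connected components, deterministically ordered.

    Components are sorted by size (descending) then by their
    lexicographically smallest member; members are sorted within each.
    """
    components = [sorted(c) for c in nx.connected_components(net.graph)]
    return sorted(components, key=lambda c: (-len(c), c[0]))


def modules_frame(net: HitNetwork) -> pd.DataFrame:
    rows = [
        {"module_id": i + 1, "size": len(members), "members": ";".join(members)}
        for i, members in enumerate(net.modules)
    ]
    return pd.DataFrame(rows, columns=["module_id", "size", "members"])


def write_graphml(net: HitNetwork, path: str | Path) -> None:
    nx.write_graphml(net.graph, path)


def write_sif(net: HitNetwork, path: str | Path) -> None:
    """Simple-interaction-format export; singletons emitted as bare nodes."""
    with open(path, "w") as fh:
        for a, b in sorted(net.edges):
            fh.write(f"{a}\tpp\t{b}\n")
        linked = {g for e in net.edges for g in e}
        for node in sorted(net.nodes - linked):
            fh.write(f"{node}\n")
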