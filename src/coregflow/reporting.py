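"""Co-regulatory graph construction, node extraction and exports.

Nodes are the up/down-classified differentially influential regulators
(DIRs), sized by their target counts; edges connect DIR pairs sharing at
least ``min_shared_targets`` local programs and are typed by the kind of
support: ``ppi_evidence`` (protein-interaction record), ``transcriptional_
evidence`` (either regulator's own gene is an evidenced target of the
other) and ``inferred_only`` (co-occurrence in inferred programs alone).
A pair can carry several types; the direction of transcriptional evidence
is retained as an edge attribute.

Exports: GraphML (round-trippable, attributes preserved) and SIF (one row
per edge type; transcriptional rows are written per evidenced direction).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .io import CoregflowError, EvidenceSet, ExpressionDataset, RegulatoryNetwork

__all__ = [
    "CoRegulatoryGraph",
    "build_coreg_graph",
    "extract_regulatory_node",
    "mean_group_influence",
    "export_graph",
    "read_graphml",
    "target_matrix",
]

EDGE_TYPES = ("ppi_evidence", "transcriptional_evidence", "inferred_only")


@dataclass
class CoRegulatoryGraph:
    """DIR nodes and typed cooperation edges.

    ``nodes``: regulator -> {n_targets, delta_influence, class};
    ``edges``: sorted pair tuple -> {types (frozenset), shared_target_count,
    tx_direction ("a>b" / "b>a" / "both" / "")}.
    """

    nodes: dict[str, dict] = field(default_factory=dict)
    edges: dict[tuple[str, str], dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (a, b), attrs in self.edges.items():
            if a not in self.nodes or b not in self.nodes:
                raise CoregflowError(f"edge ({a}, {b}) references unknown node")
            if not attrs["types"]:
                raise CoregflowError(f"edge ({a}, {b}) carries no type")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n, attrs in self.nodes.items():
            g.add_node(
                n,
                n_targets=int(attrs["n_targets"]),
                delta_influence=float(attrs["delta_influence"]),
                **{"class": str(attrs["class"])},
            )
        for (a, b), attrs in self.edges.items():
            g.add_edge(
                a,
                b,
                types="|".join(sorted(attrs["types"])),
                shared_target_count=int(attrs["shared_target_count"]),
                tx_direction=str(attrs.get("tx_direction", "")),
            )
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "CoRegulatoryGraph":
        nodes = {
            n: {
                "n_targets": int(d["n_targets"]),
                "delta_influence": float(d["delta_influence"]),
                "class": str(d["class"]),
            }
            for n, d in g.nodes(data=True)
        }
        edges = {}
        for a, b, d in g.edges(data=True):
            a, b = sorted((a, b))
            edges[(a, b)] = {
                "types": frozenset(d["types"].split("|")),
                "shared_target_count": int(d["shared_target_count"]),
                "tx_direction": str(d.get("tx_direction", "")),
            }
        return cls(nodes, edges)


def build_coreg_graph(
    network: RegulatoryNetwork,
    dirs: pd.DataFrame,
    evidence: EvidenceSet,
    min_shared_targets: int = 1,
) -> CoRegulatoryGraph:
    """Typed co-regulator graph over the up/down DIRs.

    An edge joins two DIRs co-occurring in at least ``min_shared_targets``
    programs; ``n_targets`` per node is the regulator's regulon size
    |A^r union I^r| in the network.
    """
    classified = dirs[dirs["class"].isin(("up", "down"))]
    view = network.regulon_view()
    nodes: dict[str, dict] = {}
    for _, row in classified.iterrows():
        r = row["feature_id"]
        a, i = view.get(r, (set(), set()))
        nodes[r] = {
            "n_targets": len(a | i),
            "delta_influence": float(row["delta"]),
            "class": str(row["class"]),
        }

    shared: dict[tuple[str, str], int] = {}
    node_set = set(nodes)
    for prog in network.programs.values():
        members = sorted(prog.regulators & node_set)
        for a, b in itertools.combinations(members, 2):
            shared[(a, b)] = shared.get((a, b), 0) + 1

    tf_pairs = evidence.tf_target_pairs()
    ppi_pairs = evidence.ppi_pairs()
    edges: dict[tuple[str, str], dict] = {}
    for (a, b), count in shared.items():
        if count < min_shared_targets:
            continue
        types = set()
        if (a, b) in ppi_pairs:
            types.add("ppi_evidence")
        a_to_b = (a, b) in tf_pairs
        b_to_a = (b, a) in tf_pairs
        tx_direction = ""
        if a_to_b or b_to_a:
            types.add("transcriptional_evidence")
            tx_direction = "both" if (a_to_b and b_to_a) else ("a>b" if a_to_b else "b>a")
        if not types:
            types.add("inferred_only")
        edges[(a, b)] = {
            "types": frozenset(types),
            "shared_target_count": count,
            "tx_direction": tx_direction,
        }
    return CoRegulatoryGraph(nodes, edges)


def extract_regulatory_node(
    graph: CoRegulatoryGraph, direction: str = "up"
) -> tuple[set[str], int]:
    """Largest connected component among ``direction``-classified DIRs.

    Ties between equally sized components break toward the component with
    the lexicographically smallest member.  Returns (members, size); an
    empty node if no DIR carries the class.
    """
    sub = nx.Graph()
    members = [n for n, d in graph.nodes.items() if d["class"] == direction]
    sub.add_nodes_from(members)
    msub = set(members)
    for (a, b) in graph.edges:
        if a in msub and b in msub:
            sub.add_edge(a, b)
    if not members:
        return set(), 0
    comps = sorted(
        (set(c) for c in nx.connected_components(sub)),
        key=lambda c: (-len(c), min(c)),
    )
    best = comps[0]
    return best, len(best)


def mean_group_influence(members: set[str], dirs: pd.DataFrame) -> float:
    """Arithmetic mean of the members' influence differences (delta)."""
    if not members:
        raise CoregflowError("empty regulatory node")
    sel = dirs[dirs["feature_id"].isin(members)]
    if len(sel) != len(members):
        missing = members - set(sel["feature_id"])
        raise CoregflowError(f"members missing from DIR table: {sorted(missing)[:5]}")
    return float(sel["delta"].mean())


def export_graph(graph: CoRegulatoryGraph, path, format: str) -> None:
    """Write the graph as ``graphml`` or ``sif``.

    GraphML keeps all node/edge attributes and re-imports to an equal
    graph.  SIF writes one row per edge type; transcriptional-evidence rows
    follow the evidenced direction (one row per direction).
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(graph.to_networkx(), path)
    elif format == "sif":
        lines = []
        for (a, b) in sorted(graph.edges):
            attrs = graph.edges[(a, b)]
            for t in sorted(attrs["types"]):
                if t == "transcriptional_evidence":
                    direction = attrs.get("tx_direction", "")
                    if direction in ("a>b", "both"):
                        lines.append(f"{a}\t{t}\t{b}")
                    if direction in ("b>a", "both"):
                        lines.append(f"{b}\t{t}\t{a}")
                else:
                    lines.append(f"{a}\t{t}\t{b}")
        path.write_text("".join(ln + "\n" for ln in lines))
    else:
        raise CoregflowError(f"unknown graph format {format!r}")


def read_graphml(path) -> CoRegulatoryGraph:
    return CoRegulatoryGraph.from_networkx(nx.read_graphml(path))


def target_matrix(
    network: RegulatoryNetwork,
    expr: ExpressionDataset,
    degs: pd.DataFrame,
    regulator_subset: set[str],
    top_n: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression sub-matrix of a regulator subset's DEG-classified targets.

    Rows are the union of the subset's regulon genes intersected with
    up/down DEGs, ordered by class (up first) then |log2_fc| descending
    (ties by gene id); ``top_n`` truncates to the most regulated targets.
    Returns (sub-matrix, direction table) where the direction table has one
    row per (gene, regulator) with sign +1 for activation, -1 for
    repression — a gene may carry both annotations from different subset
    members.
    """
    view = network.regulon_view()
    unknown = regulator_subset - set(view)
    if unknown:
        raise CoregflowError(f"regulators not in network: {sorted(unknown)[:5]}")
    regulon_genes: set[str] = set()
    for r in regulator_subset:
        a, i = view[r]
        regulon_genes |= a | i
    cls = degs.set_index("feature_id")
    selected = [
        g
        for g in regulon_genes
        if g in cls.index and cls.loc[g, "class"] in ("up", "down")
    ]
    order_key = {
        g: (0 if cls.loc[g, "class"] == "up" else 1, -abs(cls.loc[g, "log2_fc"]), g)
        for g in selected
    }
    selected.sort(key=order_key.__getitem__)
    if top_n is not None:
        selected = selected[:top_n]
    available = [g for g in selected if g in set(expr.gene_ids)]
    sub = expr.values.loc[available]
    rows = []
    for g in selected:
        for r in sorted(regulator_subset):
            a, i = view[r]
            if g in a:
                rows.append({"gene": g, "regulator": r, "sign": 1})
            if g in i:
                rows.append({"gene": g, "regulator": r, "sign": -1})
    return sub, pd.DataFrame(rows, columns=["gene", "regulator", "sign"])
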