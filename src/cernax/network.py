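"""Direction-constrained tripartite ceRNA network assembly.

A ceRNA network joins lncRNA, miRNA and mRNA nodes of one cross-cancer
category (shared / semi-shared / specific) through candidate interaction
pairs, under the ceRNA direction rule: the miRNA must be dysregulated in
the direction opposite to both its lncRNA and mRNA partners.  Edges carry
the set of cancers in which both endpoints are co-dysregulated (the
intersection of the endpoints' member-cancer sets), which must be
non-empty.  After candidate edges are laid down, the graph is pruned to a
fixed point: every miRNA must keep at least one lncRNA-side and one
mRNA-side edge, and no node may be isolated.

miRNA-mRNA candidate pairs are evidence-filtered first (minimum number of
supporting prediction databases and minimum CLIP-experiment count, both
inclusive); lncRNA-miRNA pairs carry no evidence filter.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .cross_cancer import CategoryAssignment

log = logging.getLogger(__name__)

LNC_MI = "lnc_mi"
MI_M = "mi_m"

PAIR_COLUMNS = {LNC_MI: ["lncRNA", "miRNA"], MI_M: ["miRNA", "mRNA"]}
EVIDENCE_COLUMNS = ["support_db_count", "clip_exp_count"]


@dataclasses.dataclass
class InteractionTable:
    """Deduplicated candidate pairs of one kind.

    ``pairs`` columns are ``lncRNA, miRNA`` for kind ``lnc_mi`` and
    ``miRNA, mRNA, support_db_count, clip_exp_count`` for kind ``mi_m``.
    """

    kind: str
    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        if self.kind not in PAIR_COLUMNS:
            raise ValueError(f"kind must be one of {sorted(PAIR_COLUMNS)}, got {self.kind!r}")
        cols = PAIR_COLUMNS[self.kind]
        expected = cols + (EVIDENCE_COLUMNS if self.kind == MI_M else [])
        missing = [c for c in expected if c not in self.pairs.columns]
        if missing:
            raise ValueError(f"{self.kind} table missing columns {missing}")
        self.pairs = self.pairs[expected].drop_duplicates(subset=cols, ignore_index=True)
        if self.kind == MI_M:
            ev = self.pairs[EVIDENCE_COLUMNS]
            if (ev.to_numpy() < 0).any():
                raise ValueError("evidence counts must be nonnegative")

    def __len__(self) -> int:
        return len(self.pairs)


def filter_mi_m_pairs(table: InteractionTable, min_db: int, min_clip: int) -> InteractionTable:
    """Keep miRNA-mRNA pairs with support_db_count >= min_db and
    clip_exp_count >= min_clip (boundaries inclusive)."""
    if table.kind != MI_M:
        raise ValueError("evidence filter applies to mi_m tables only")
    kept = table.pairs[
        (table.pairs["support_db_count"] >= min_db)
        & (table.pairs["clip_exp_count"] >= min_clip)
    ].reset_index(drop=True)
    log.info(
        "filter_mi_m_pairs: %d of %d pairs survive (min_db=%d, min_clip=%d)",
        len(kept), len(table), min_db, min_clip,
    )
    return InteractionTable(MI_M, kept)


CLASS_OF_KIND = {LNC_MI: ("lncRNA", "miRNA"), MI_M: ("miRNA", "mRNA")}


class CeRNANetwork:
    """Tripartite lncRNA-miRNA-mRNA graph with typed, cancer-annotated edges.

    Thin wrapper over an undirected :class:`networkx.Graph`.  Node
    attributes: ``rna_class``, ``direction`` (up/down), ``category``,
    ``cancers`` (frozenset), optional ``is_key``.  Edge attributes:
    ``kind`` (lnc_mi/mi_m), ``cancers`` (frozenset).
    """

    def __init__(self, cancer_universe: Sequence[str] = ()) -> None:
        self.graph = nx.Graph()
        self.cancer_universe = tuple(cancer_universe)

    # -- construction -----------------------------------------------------
    def add_node(self, gene: str, rna_class: str, direction: str, category: str,
                 cancers: Iterable[str], **extra) -> None:
        self.graph.add_node(
            gene, rna_class=rna_class, direction=direction, category=category,
            cancers=frozenset(cancers), **extra,
        )

    def add_edge(self, a: str, b: str, kind: str, cancers: Iterable[str]) -> None:
        self.graph.add_edge(a, b, kind=kind, cancers=frozenset(cancers))

    def copy(self) -> "CeRNANetwork":
        out = CeRNANetwork(self.cancer_universe)
        out.graph = self.graph.copy()
        return out

    # -- queries ----------------------------------------------------------
    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def nodes_of_class(self, rna_class: str) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["rna_class"] == rna_class]

    def neighbors_by_kind(self, node: str, kind: str) -> list[str]:
        return [
            v for v in self.graph.neighbors(node)
            if self.graph.edges[node, v]["kind"] == kind
        ]

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def edge_set(self) -> set[tuple[str, str, str]]:
        return {
            (min(u, v), max(u, v), d["kind"]) for u, v, d in self.graph.edges(data=True)
        }

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        """Raise if any structural invariant is violated."""
        for u, v, d in self.graph.edges(data=True):
            cu, cv = self.nodes[u]["rna_class"], self.nodes[v]["rna_class"]
            if {cu, cv} != set(CLASS_OF_KIND[d["kind"]]):
                raise AssertionError(f"edge {u}-{v} classes {cu}/{cv} invalid for {d['kind']}")
            if self.nodes[u]["direction"] == self.nodes[v]["direction"]:
                raise AssertionError(f"edge {u}-{v} joins same-direction nodes")
            if not d["cancers"]:
                raise AssertionError(f"edge {u}-{v} has empty cancer set")
        for n, d in self.graph.nodes(data=True):
            if self.graph.degree(n) == 0:
                raise AssertionError(f"isolated node {n}")
            if d["rna_class"] == "miRNA":
                if not self.neighbors_by_kind(n, LNC_MI) or not self.neighbors_by_kind(n, MI_M):
                    raise AssertionError(f"miRNA {n} lacks a lncRNA or mRNA side")

    # -- pruning ----------------------------------------------------------
    def prune(self) -> "CeRNANetwork":
        """Iteratively drop miRNAs missing either side and isolated
        lnc/mRNAs until a fixed point (order-independent)."""
        g = self.graph
        changed = True
        while changed:
            changed = False
            drop = []
            for n, d in g.nodes(data=True):
                if d["rna_class"] == "miRNA":
                    kinds = {g.edges[n, v]["kind"] for v in g.neighbors(n)}
                    if kinds != {LNC_MI, MI_M}:
                        drop.append(n)
                elif g.degree(n) == 0:
                    drop.append(n)
            if drop:
                g.remove_nodes_from(drop)
                changed = True
        return self


def _candidate_nodes(
    assignments: Sequence[CategoryAssignment],
    category: str,
    cancer_scope: str | None,
) -> dict[str, CategoryAssignment]:
    """One assignment per gene: requested category, optionally restricted to
    assignments whose member set contains the scope cancer.  When a gene has
    several qualifying assignments the one with the larger member set wins
    (tie -> up), keeping node direction single-valued and deterministic."""
    chosen: dict[str, CategoryAssignment] = {}
    for a in assignments:
        if a.category != category:
            continue
        if cancer_scope is not None and cancer_scope not in a.members:
            continue
        prev = chosen.get(a.gene)
        if prev is None or (len(a.members), a.sign == "up") > (len(prev.members), prev.sign == "up"):
            chosen[a.gene] = a
    return chosen


def assemble_network(
    assignments_by_class: Mapping[str, Sequence[CategoryAssignment]],
    lnc_mi: InteractionTable,
    mi_m: InteractionTable,
    category: str,
    cancer_scope: str | None = None,
    cancer_universe: Sequence[str] = (),
) -> CeRNANetwork:
    """Assemble the tripartite network of one category.

    ``mi_m`` must already be evidence-filtered.  Candidate edges require
    both endpoints to carry the requested category, opposite directions,
    and at least one common member cancer; edge cancer set = intersection
    of the endpoints' member sets.  The result is pruned so every miRNA is
    two-sided and no node is isolated.  Empty assignments yield an empty
    network with a warning.
    """
    if lnc_mi.kind != LNC_MI or mi_m.kind != MI_M:
        raise ValueError("pair tables passed in the wrong order")
    candidates = {
        rna_class: _candidate_nodes(assignments_by_class.get(rna_class, ()), category, cancer_scope)
        for rna_class in ("lncRNA", "miRNA", "mRNA")
    }
    net = CeRNANetwork(cancer_universe)
    if not any(candidates.values()):
        log.warning("assemble_network(%s): no candidate nodes; empty network", category)
        return net

    def try_edge(a: CategoryAssignment, b: CategoryAssignment, kind: str) -> None:
        if a.sign == b.sign:
            return
        common = a.members & b.members
        if not common:
            return
        for x in (a, b):
            if x.gene not in net.graph:
                net.add_node(x.gene, x.rna_class, x.sign, x.category, x.members)
        net.add_edge(a.gene, b.gene, kind, common)

    for _, row in lnc_mi.pairs.iterrows():
        a = candidates["lncRNA"].get(row["lncRNA"])
        b = candidates["miRNA"].get(row["miRNA"])
        if a is not None and b is not None:
            try_edge(a, b, LNC_MI)
    for _, row in mi_m.pairs.iterrows():
        a = candidates["miRNA"].get(row["miRNA"])
        b = candidates["mRNA"].get(row["mRNA"])
        if a is not None and b is not None:
            try_edge(a, b, MI_M)
    net.prune()
    log.info(
        "assemble_network(%s%s): %d nodes, %d edges",
        category, f", scope={cancer_scope}" if cancer_scope else "",
        net.graph.number_of_nodes(), net.graph.number_of_edges(),
    )
    return net


def per_cancer_portion(network: CeRNANetwork, cancer: str) -> CeRNANetwork:
    """Induced subgraph of edges whose cancer set contains ``cancer``,
    re-pruned to restore miRNA two-sidedness and drop isolates."""
    if network.cancer_universe and cancer not in network.cancer_universe:
        raise ValueError(f"unknown cancer {cancer!r}; panel is {list(network.cancer_universe)}")
    out = network.copy()
    out.graph.remove_edges_from(
        [
            (u, v) for u, v, d in network.graph.edges(data=True)
            if cancer not in d["cancers"]
        ]
    )
    return out.prune()


def extract_sub_cerna(
    network: CeRNANetwork,
    key_mrnas: Iterable[str],
    key_lncrnas: Iterable[str] = (),
) -> CeRNANetwork:
    """Neighborhood of the key genes: key mRNAs, miRNAs adjacent to at
    least one key mRNA, and lncRNAs adjacent to those miRNAs.  Key genes
    absent from the network are logged and ignored; key lncRNAs present in
    the result are flagged ``is_key``."""
    key_mrnas, key_lncrnas = set(key_mrnas), set(key_lncrnas)
    for missing in sorted((key_mrnas | key_lncrnas) - set(network.graph.nodes)):
        log.warning("extract_sub_cerna: key gene %r not in network; ignored", missing)
    mrnas = {g for g in key_mrnas if g in network.graph and network.nodes[g]["rna_class"] == "mRNA"}
    mirnas = {
        mi for m in mrnas for mi in network.neighbors_by_kind(m, MI_M)
    }
    lncs = {
        lnc for mi in mirnas for lnc in network.neighbors_by_kind(mi, LNC_MI)
    }
    keep = mrnas | mirnas | lncs
    out = network.copy()
    out.graph.remove_nodes_from(set(network.graph.nodes) - keep)
    # drop mi_m edges to non-key mRNAs already removed; also edges between
    # kept nodes are inherited — restrict mi_m edges to key mRNAs only
    out.prune()
    for gene in out.graph.nodes:
        out.graph.nodes[gene]["is_key"] = (
            gene in key_mrnas or gene in key_lncrnas
        )
    return out


def network_summary(network: CeRNANetwork) -> pd.DataFrame:
    """Node tallies by (rna_class, direction) and edge tallies by kind."""
    rows = []
    for rna_class in ("lncRNA", "miRNA", "mRNA"):
        for direction in ("up", "down"):
            n = sum(
                1 for _, d in network.graph.nodes(data=True)
                if d["rna_class"] == rna_class and d["direction"] == direction
            )
            rows.append({"entity": "node", "kind": rna_class, "direction": direction, "count": n})
    for kind in (LNC_MI, MI_M):
        n = sum(1 for _, _, d in network.graph.edges(data=True) if d["kind"] == kind)
        rows.append({"entity": "edge", "kind": kind, "direction": "", "count": n})
    return pd.DataFrame(rows, columns=["entity", "kind", "direction", "count"])
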