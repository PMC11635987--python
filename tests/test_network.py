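import itertools

import numpy as np
import pandas as pd
import pytest

from cernax import (
    CeRNANetwork,
    InteractionTable,
    assemble_network,
    extract_sub_cerna,
    filter_mi_m_pairs,
    network_summary,
    per_cancer_portion,
)
from cernax.cross_cancer import CategoryAssignment
from cernax.network import LNC_MI, MI_M

CANCERS = ("ESCA", "STAD", "LIHC", "COAD")


def lnc_mi_table(pairs):
    return InteractionTable(LNC_MI, pd.DataFrame(pairs, columns=["lncRNA", "miRNA"]))


def mi_m_table(pairs, support=5, clip=3):
    rows = [
        {"miRNA": mi, "mRNA": m, "support_db_count": support, "clip_exp_count": clip}
        for mi, m in pairs
    ]
    return InteractionTable(
        MI_M, pd.DataFrame(rows, columns=["miRNA", "mRNA", "support_db_count", "clip_exp_count"])
    )


def shared_assignment(gene, rna_class, sign):
    return CategoryAssignment(gene, rna_class, sign, "shared", frozenset(CANCERS))


class TestEvidenceFilter:
    @pytest.mark.parametrize(
        "support,clip,kept",
        [(2, 1, True), (1, 5, False), (7, 0, False), (2, 0, False), (7, 10, True)],
    )
    def test_inclusive_boundaries(self, support, clip, kept):
        table = mi_m_table([("miR-1", "GENE1")], support=support, clip=clip)
        filtered = filter_mi_m_pairs(table, min_db=2, min_clip=1)
        assert (len(filtered) == 1) is kept

    def test_wrong_kind_rejected(self):
        with pytest.raises(ValueError, match="mi_m"):
            filter_mi_m_pairs(lnc_mi_table([("L1", "M1")]), 2, 1)

    def test_monotone_in_thresholds(self, rng):
        rows = [
            {
                "miRNA": f"mi{i % 6}", "mRNA": f"m{i}",
                "support_db_count": int(rng.integers(0, 8)),
                "clip_exp_count": int(rng.integers(0, 6)),
            }
            for i in range(60)
        ]
        table = InteractionTable(MI_M, pd.DataFrame(rows))
        previous = None
        for min_db in range(8):
            kept = set(map(tuple, filter_mi_m_pairs(table, min_db, 1).pairs.to_numpy()))
            if previous is not None:
                assert kept <= previous
            previous = kept


class TestAssembly:
    def test_minimal_valid_triple(self):
        assignments = {
            "lncRNA": [shared_assignment("lncA", "lncRNA", "up")],
            "miRNA": [shared_assignment("miR1", "miRNA", "down")],
            "mRNA": [shared_assignment("X", "mRNA", "up")],
        }
        net = assemble_network(
            assignments, lnc_mi_table([("lncA", "miR1")]), mi_m_table([("miR1", "X")]),
            "shared", cancer_universe=CANCERS,
        )
        assert len(net) == 3 and net.graph.number_of_edges() == 2
        net.validate()

    def test_direction_violation_prunes_everything(self):
        assignments = {
            "lncRNA": [shared_assignment("lncA", "lncRNA", "up")],
            "miRNA": [shared_assignment("miR1", "miRNA", "down")],
            "mRNA": [shared_assignment("X", "mRNA", "down")],  # same sign as miRNA
        }
        net = assemble_network(
            assignments, lnc_mi_table([("lncA", "miR1")]), mi_m_table([("miR1", "X")]),
            "shared", cancer_universe=CANCERS,
        )
        assert len(net) == 0

    def test_empty_assignments_give_empty_network(self):
        net = assemble_network(
            {}, lnc_mi_table([("lncA", "miR1")]), mi_m_table([("miR1", "X")]), "shared"
        )
        assert len(net) == 0

    @staticmethod
    def _random_instance(rng, category="semi_shared"):
        """Random assignments with unique genes per class plus random pairs."""
        def members(category):
            if category == "shared":
                return frozenset(CANCERS)
            if category == "specific":
                return frozenset([CANCERS[rng.integers(4)]])
            k = int(rng.integers(2, 4))
            return frozenset(rng.choice(CANCERS, size=k, replace=False))

        assignments = {"lncRNA": [], "miRNA": [], "mRNA": []}
        genes = {"lncRNA": [], "miRNA": [], "mRNA": []}
        for rna_class, prefix, n in (
            ("lncRNA", "L", 12), ("miRNA", "M", 8), ("mRNA", "R", 20)
        ):
            for i in range(n):
                gene = f"{prefix}{i}"
                sign = "up" if rng.random() < 0.5 else "down"
                assignments[rna_class].append(
                    CategoryAssignment(gene, rna_class, sign, category, members(category))
                )
                genes[rna_class].append(gene)
        lnc_mi_pairs = {
            (genes["lncRNA"][rng.integers(12)], genes["miRNA"][rng.integers(8)])
            for _ in range(25)
        }
        mi_m_pairs = {
            (genes["miRNA"][rng.integers(8)], genes["mRNA"][rng.integers(20)])
            for _ in range(35)
        }
        return assignments, sorted(lnc_mi_pairs), sorted(mi_m_pairs)

    @staticmethod
    def _brute_force(assignments, lnc_mi_pairs, mi_m_pairs, category):
        """Independent assembly: enumerate pairs, apply the three predicates,
        prune by repeated full scans."""
        chosen = {}
        for rna_class, items in assignments.items():
            for a in items:
                if a.category == category:
                    chosen[a.gene] = a
        edges = {}
        for a_id, b_id, kind in (
            [(l, m, LNC_MI) for l, m in lnc_mi_pairs]
            + [(m, r, MI_M) for m, r in mi_m_pairs]
        ):
            a, b = chosen.get(a_id), chosen.get(b_id)
            if a is None or b is None or a.sign == b.sign:
                continue
            common = a.members & b.members
            if common:
                edges[(a_id, b_id, kind)] = common
        while True:
            nodes = {g for (a, b, _) in edges for g in (a, b)}
            drop = set()
            for gene in nodes:
                a = chosen[gene]
                if a.rna_class == "miRNA":
                    has_lnc = any(k == LNC_MI and b == gene for (_, b, k) in edges)
                    has_m = any(k == MI_M and x == gene for (x, _, k) in edges)
                    if not (has_lnc and has_m):
                        drop.add(gene)
            if not drop:
                break
            edges = {
                key: v for key, v in edges.items() if key[0] not in drop and key[1] not in drop
            }
        return {
            (min(a, b), max(a, b), k) for (a, b, k) in edges
        }

    @pytest.mark.parametrize("category", ["shared", "semi_shared", "specific"])
    def test_matches_brute_force(self, category):
        rng = np.random.default_rng(7)
        for trial in range(8):
            assignments, lnc_mi_pairs, mi_m_pairs = self._random_instance(rng, category)
            net = assemble_network(
                assignments, lnc_mi_table(lnc_mi_pairs), mi_m_table(mi_m_pairs),
                category, cancer_universe=CANCERS,
            )
            expected = self._brute_force(assignments, lnc_mi_pairs, mi_m_pairs, category)
            assert net.edge_set() == expected, trial
            net.validate()

    def test_edge_cancer_set_is_member_intersection(self):
        assignments = {
            "lncRNA": [CategoryAssignment("L", "lncRNA", "up", "semi_shared",
                                          frozenset({"ESCA", "STAD", "LIHC"}))],
            "miRNA": [CategoryAssignment("M", "miRNA", "down", "semi_shared",
                                         frozenset({"STAD", "LIHC", "COAD"}))],
            "mRNA": [CategoryAssignment("R", "mRNA", "up", "semi_shared",
                                        frozenset({"STAD", "COAD"}))],
        }
        net = assemble_network(
            assignments, lnc_mi_table([("L", "M")]), mi_m_table([("M", "R")]),
            "semi_shared", cancer_universe=CANCERS,
        )
        assert net.edges["L", "M"]["cancers"] == frozenset({"STAD", "LIHC"})
        assert net.edges["M", "R"]["cancers"] == frozenset({"STAD", "COAD"})

    def test_assembly_monotone_in_evidence(self, rng):
        assignments, lnc_mi_pairs, mi_m_pairs = self._random_instance(rng, "shared")
        rows = [
            {
                "miRNA": mi, "mRNA": m,
                "support_db_count": int(rng.integers(0, 8)),
                "clip_exp_count": int(rng.integers(0, 6)),
            }
            for mi, m in mi_m_pairs
        ]
        raw = InteractionTable(MI_M, pd.DataFrame(rows))
        previous = None
        for min_db in (0, 2, 4, 6):
            net = assemble_network(
                assignments, lnc_mi_table(lnc_mi_pairs),
                filter_mi_m_pairs(raw, min_db, 1), "shared", cancer_universe=CANCERS,
            )
            edges = net.edge_set()
            if previous is not None:
                assert edges <= previous
            previous = edges


def build_semi_network():
    """Small semi-shared network with heterogeneous edge cancer sets."""
    assignments = {
        "lncRNA": [
            CategoryAssignment("L1", "lncRNA", "up", "semi_shared", frozenset({"STAD", "LIHC"})),
            CategoryAssignment("L2", "lncRNA", "up", "semi_shared", frozenset({"ESCA", "COAD"})),
        ],
        "miRNA": [
            CategoryAssignment("M1", "miRNA", "down", "semi_shared",
                               frozenset({"STAD", "LIHC", "COAD", "ESCA"}) - frozenset({"COAD"})),
            CategoryAssignment("M2", "miRNA", "down", "semi_shared", frozenset({"ESCA", "COAD"})),
        ],
        "mRNA": [
            CategoryAssignment("R1", "mRNA", "up", "semi_shared", frozenset({"STAD", "LIHC"})),
            CategoryAssignment("R2", "mRNA", "up", "semi_shared", frozenset({"ESCA", "COAD"})),
        ],
    }
    return assemble_network(
        assignments,
        lnc_mi_table([("L1", "M1"), ("L2", "M2")]),
        mi_m_table([("M1", "R1"), ("M2", "R2")]),
        "semi_shared", cancer_universe=CANCERS,
    )


class TestPortions:
    def test_edge_retained_iff_cancer_in_set(self):
        net = build_semi_network()
        stad = per_cancer_portion(net, "STAD")
        assert ("L1", "M1", LNC_MI) in stad.edge_set()
        coad = per_cancer_portion(net, "COAD")
        assert ("L1", "M1", LNC_MI) not in coad.edge_set()
        assert ("L2", "M2", LNC_MI) in coad.edge_set()

    def test_shared_portion_is_full_network(self):
        assignments = {
            "lncRNA": [shared_assignment("L", "lncRNA", "up")],
            "miRNA": [shared_assignment("M", "miRNA", "down")],
            "mRNA": [shared_assignment("R", "mRNA", "up")],
        }
        net = assemble_network(
            assignments, lnc_mi_table([("L", "M")]), mi_m_table([("M", "R")]),
            "shared", cancer_universe=CANCERS,
        )
        for cancer in CANCERS:
            assert per_cancer_portion(net, cancer).edge_set() == net.edge_set()

    def test_unknown_cancer_rejected(self):
        with pytest.raises(ValueError, match="BRCA"):
            per_cancer_portion(build_semi_network(), "BRCA")

    def test_portions_cover_full_edge_set(self):
        net = build_semi_network()
        union = set()
        for cancer in CANCERS:
            union |= per_cancer_portion(net, cancer).edge_set()
        assert union == net.edge_set()


class TestSubCeRNA:
    def _network(self):
        assignments = {
            "lncRNA": [shared_assignment("lncA", "lncRNA", "up"),
                       shared_assignment("lncB", "lncRNA", "up")],
            "miRNA": [shared_assignment("miR1", "miRNA", "down"),
                      shared_assignment("miR2", "miRNA", "down")],
            "mRNA": [shared_assignment("X", "mRNA", "up"),
                     shared_assignment("Y", "mRNA", "up")],
        }
        return assemble_network(
            assignments,
            lnc_mi_table([("lncA", "miR1"), ("lncB", "miR2")]),
            mi_m_table([("miR1", "X"), ("miR2", "Y")]),
            "shared", cancer_universe=CANCERS,
        )

    def test_key_mrna_neighborhood(self):
        sub = extract_sub_cerna(self._network(), key_mrnas={"X"})
        assert set(sub.graph.nodes) == {"lncA", "miR1", "X"}
        assert sub.nodes["X"]["is_key"]
        sub.validate()

    def test_empty_key_set_gives_empty_network(self):
        assert len(extract_sub_cerna(self._network(), key_mrnas=set())) == 0

    def test_missing_key_gene_ignored(self):
        sub = extract_sub_cerna(self._network(), key_mrnas={"X", "NOT_THERE"})
        assert set(sub.graph.nodes) == {"lncA", "miR1", "X"}

    def test_matches_brute_force_neighborhood(self):
        rng = np.random.default_rng(11)
        for _ in range(6):
            assignments, lnc_mi_pairs, mi_m_pairs = TestAssembly._random_instance(rng, "shared")
            net = assemble_network(
                assignments, lnc_mi_table(lnc_mi_pairs), mi_m_table(mi_m_pairs),
                "shared", cancer_universe=CANCERS,
            )
            mrnas = [n for n, d in net.graph.nodes(data=True) if d["rna_class"] == "mRNA"]
            keys = set(rng.choice(mrnas, size=min(3, len(mrnas)), replace=False)) if mrnas else set()
            sub = extract_sub_cerna(net, keys)
            # brute force: scan all edges
            mis = {
                mi for key in keys for mi in net.graph.neighbors(key)
                if net.graph.edges[key, mi]["kind"] == MI_M
            }
            lncs = {
                l for mi in mis for l in net.graph.neighbors(mi)
                if net.graph.edges[mi, l]["kind"] == LNC_MI
            }
            expected_edges = set()
            for a, b, d in net.graph.edges(data=True):
                u, v = min(a, b), max(a, b)
                if d["kind"] == MI_M and {a, b} & keys and {a, b} & mis:
                    expected_edges.add((u, v, MI_M))
                if d["kind"] == LNC_MI and {a, b} & lncs and {a, b} & mis:
                    expected_edges.add((u, v, LNC_MI))
            # prune: every miRNA in the expectation keeps both sides by
            # construction (it has a key mRNA and at least one lncRNA) unless
            # it lacks a lncRNA partner
            two_sided = {
                mi for mi in mis
                if any(k == LNC_MI and mi in (a, b) for a, b, k in expected_edges)
            }
            expected_edges = {
                (a, b, k) for a, b, k in expected_edges if {a, b} & mis <= two_sided
            }
            assert sub.edge_set() == expected_edges


class TestPruneAndSummary:
    def test_prune_is_insertion_order_independent(self):
        rng = np.random.default_rng(3)
        assignments, lnc_mi_pairs, mi_m_pairs = TestAssembly._random_instance(rng, "shared")
        reference = None
        for _ in range(4):
            order = rng.permutation(len(lnc_mi_pairs))
            shuffled = [lnc_mi_pairs[i] for i in order]
            net = assemble_network(
                assignments, lnc_mi_table(shuffled), mi_m_table(mi_m_pairs),
                "shared", cancer_universe=CANCERS,
            )
            if reference is None:
                reference = net.edge_set()
            assert net.edge_set() == reference

    def test_summary_minimal_network(self):
        assignments = {
            "lncRNA": [shared_assignment("L", "lncRNA", "up")],
            "miRNA": [shared_assignment("M", "miRNA", "down")],
            "mRNA": [shared_assignment("R", "mRNA", "up")],
        }
        net = assemble_network(
            assignments, lnc_mi_table([("L", "M")]), mi_m_table([("M", "R")]),
            "shared", cancer_universe=CANCERS,
        )
        summary = network_summary(net).set_index(["entity", "kind", "direction"])["count"]
        assert summary[("node", "lncRNA", "up")] == 1
        assert summary[("node", "miRNA", "down")] == 1
        assert summary[("node", "mRNA", "up")] == 1
        assert summary[("node", "lncRNA", "down")] == 0
        assert summary[("edge", LNC_MI, "")] == 1
        assert summary[("edge", MI_M, "")] == 1

    def test_summary_empty_and_conserving(self):
        empty = network_summary(CeRNANetwork())
        assert (empty["count"] == 0).all()
        net = build_semi_network()
        summary = network_summary(net)
        nodes = summary.loc[summary["entity"] == "node", "count"].sum()
        edges = summary.loc[summary["entity"] == "edge", "count"].sum()
        assert nodes == net.graph.number_of_nodes()
        assert edges == net.graph.number_of_edges()
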