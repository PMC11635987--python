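"""Hypergeometric over-representation analysis against GMT gene sets.

Given a query gene list and a user-supplied gene-set collection, each set
is scored with the upper hypergeometric tail P(X >= overlap) over a
configurable universe (by default, all genes tested for differential
expression in the run).  Sets are retained when the overlap meets a
minimum (default 2) and the raw p falls below a cutoff (default 0.01);
a BH-adjusted column is reported for information only.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

log = logging.getLogger(__name__)


@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets harmonized to a universe (out-of-universe members
    dropped with a logged count)."""

    sets: list[tuple[str, str, frozenset[str]]]
    universe: frozenset[str]

    @classmethod
    def from_sets(
        cls,
        sets: Iterable[tuple[str, str, Iterable[str]]],
        universe: Iterable[str],
    ) -> "GeneSetCollection":
        universe = frozenset(universe)
        if not universe:
            raise ValueError("empty universe")
        harmonized = []
        dropped = 0
        for name, description, genes in sets:
            genes = frozenset(genes)
            kept = genes & universe
            dropped += len(genes) - len(kept)
            harmonized.append((name, description, kept))
        if dropped:
            log.info("GeneSetCollection: dropped %d set members outside the universe", dropped)
        return cls(harmonized, universe)


def hypergeom_tail(x: int, big_k: int, n: int, big_m: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(M, K, n): drawing n genes from a
    universe of M that contains K set members.  Computed in log space by
    scipy's survival function; x = 0 returns exactly 1."""
    if not (0 <= x <= min(big_k, n) <= big_m) or big_k > big_m:
        raise ValueError(f"inconsistent arguments x={x}, K={big_k}, n={n}, M={big_m}")
    if x == 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, big_m, big_k, n))


def ora(
    query: Iterable[str],
    collection: GeneSetCollection,
    min_overlap: int = 2,
    p_cutoff: float = 0.01,
) -> pd.DataFrame:
    """Over-representation of the query in each set of the collection.

    Query genes outside the universe are dropped and logged.  Returns the
    retained sets (overlap >= min_overlap and p < p_cutoff) sorted by p
    ascending, with a BH column computed over all tested sets.
    """
    query = set(query)
    outside = query - collection.universe
    if outside:
        log.warning("ora: %d query genes outside the universe dropped", len(outside))
    query &= collection.universe
    big_m = len(collection.universe)
    n = len(query)
    rows = []
    for name, description, genes in collection.sets:
        overlap = len(query & genes)
        p = hypergeom_tail(overlap, len(genes), n, big_m)
        rows.append(
            {
                "set": name, "description": description, "set_size": len(genes),
                "overlap": overlap, "pvalue": p,
            }
        )
    table = pd.DataFrame(
        rows, columns=["set", "description", "set_size", "overlap", "pvalue"]
    )
    if len(table):
        table["bh"] = bh_adjust(table["pvalue"].to_numpy())
    else:
        table["bh"] = pd.Series(dtype=float)
    kept = table[
        (table["overlap"] >= min_overlap) & (table["pvalue"] < p_cutoff)
    ].sort_values("pvalue", kind="stable", ignore_index=True)
    log.info("ora: %d of %d sets retained (min_overlap=%d, p<%g)",
             len(kept), len(table), min_overlap, p_cutoff)
    return kept
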