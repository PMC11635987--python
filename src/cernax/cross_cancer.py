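"""Cross-cancer categorization of signed DE genes.

Each gene that is differentially expressed in at least one cancer of the
panel gets a dysregulation profile (the set of cancers where it is up and
the set where it is down).  Per sign, the profile is categorized by
cardinality: *shared* (all k cancers), *specific* (exactly one), or
*semi-shared* (2..k-1).  Up and down memberships are categorized
independently, so a gene can carry one up-assignment and one
down-assignment; a gene dysregulated everywhere with mixed signs is not
shared.  UpSet-style intersection counts are tallied exactly.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from collections.abc import Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

CATEGORIES = ("shared", "semi_shared", "specific")


@dataclasses.dataclass(frozen=True)
class DysregulationProfile:
    gene: str
    rna_class: str
    up_set: frozenset[str]
    down_set: frozenset[str]

    def __post_init__(self) -> None:
        if self.up_set & self.down_set:
            raise ValueError(
                f"gene {self.gene!r} is both up and down in "
                f"{sorted(self.up_set & self.down_set)}"
            )


@dataclasses.dataclass(frozen=True)
class CategoryAssignment:
    gene: str
    rna_class: str
    sign: str  # "up" | "down"
    category: str  # "shared" | "semi_shared" | "specific"
    members: frozenset[str]


def build_signatures(
    signed_sets_by_cancer: Mapping[str, Mapping[str, set[str]]],
    cancers: Sequence[str],
    rna_class: str,
) -> list[DysregulationProfile]:
    """One profile per gene appearing in any signed set; absent means ns.

    ``signed_sets_by_cancer[cancer]`` holds ``{"up": set, "down": set}``.
    A gene listed both up and down in the same cancer is corrupt input and
    raises.
    """
    missing = set(cancers) - set(signed_sets_by_cancer)
    if missing:
        raise ValueError(f"signed sets missing for cancers {sorted(missing)}")
    genes: set[str] = set()
    for cancer in cancers:
        sets = signed_sets_by_cancer[cancer]
        genes |= set(sets.get("up", ())) | set(sets.get("down", ()))
    profiles = []
    for gene in sorted(genes):
        up = frozenset(
            c for c in cancers if gene in signed_sets_by_cancer[c].get("up", ())
        )
        down = frozenset(
            c for c in cancers if gene in signed_sets_by_cancer[c].get("down", ())
        )
        profiles.append(DysregulationProfile(gene, rna_class, up, down))
    log.info("build_signatures %s: %d genes over %d cancers", rna_class, len(profiles), len(cancers))
    return profiles


def categorize(
    profile: DysregulationProfile, n_cancers: int
) -> list[CategoryAssignment]:
    """0, 1, or 2 assignments (one per non-empty signed set) by cardinality:
    |members| = k -> shared, = 1 -> specific, otherwise semi-shared."""
    if n_cancers < 2:
        raise ValueError("categorization needs a panel of >=2 cancers")
    out = []
    for sign, members in (("up", profile.up_set), ("down", profile.down_set)):
        if not members:
            continue
        if len(members) == n_cancers:
            category = "shared"
        elif len(members) == 1:
            category = "specific"
        else:
            category = "semi_shared"
        out.append(
            CategoryAssignment(profile.gene, profile.rna_class, sign, category, members)
        )
    return out


def categorize_all(
    profiles: Sequence[DysregulationProfile], n_cancers: int
) -> list[CategoryAssignment]:
    return [a for p in profiles for a in categorize(p, n_cancers)]


def upset_counts(
    profiles: Sequence[DysregulationProfile], cancers: Sequence[str]
) -> pd.DataFrame:
    """Exact intersection counts per sign over all non-empty cancer
    combinations; a gene is counted in exactly the combination equal to its
    member set."""
    tallies: dict[tuple[str, frozenset[str]], int] = {}
    for sign in ("up", "down"):
        for r in range(1, len(cancers) + 1):
            for combo in itertools.combinations(cancers, r):
                tallies[(sign, frozenset(combo))] = 0
    for profile in profiles:
        for sign, members in (("up", profile.up_set), ("down", profile.down_set)):
            if members:
                tallies[(sign, members)] += 1
    rows = [
        {
            "sign": sign,
            "combination": "&".join(c for c in cancers if c in members),
            "n_cancers": len(members),
            "count": count,
        }
        for (sign, members), count in tallies.items()
    ]
    out = pd.DataFrame(rows).sort_values(
        ["sign", "n_cancers", "combination"], ignore_index=True
    )
    return out


def assignments_frame(assignments: Sequence[CategoryAssignment]) -> pd.DataFrame:
    """Flat table of category assignments for writing."""
    return pd.DataFrame(
        [
            {
                "gene": a.gene,
                "rna_class": a.rna_class,
                "sign": a.sign,
                "category": a.category,
                "members": ",".join(sorted(a.members)),
            }
            for a in assignments
        ],
        columns=["gene", "rna_class", "sign", "category", "members"],
    )
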