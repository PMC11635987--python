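"""ceRNA regulatory axis mining by sign-constrained correlation.

A candidate axis is a lncRNA-miRNA-mRNA path in a (sub-)ceRNA network.
Under the ceRNA hypothesis the lncRNA sponges the miRNA and thereby
de-represses the mRNA, so across tumor samples the expected pairwise
correlation pattern is

* mRNA vs miRNA:   negative,
* miRNA vs lncRNA: negative,
* mRNA vs lncRNA:  positive,

each significant at the configured alpha (strict p < alpha).  Correlations
are Pearson on log2(normalized expression + 1) over the tumor samples
shared by the three expression matrices (Spearman available).  The filter
also runs directly on externally supplied correlation tables with the
standard column layout (cancer, mRNA, miRNA, lncRNA, r_mm, p_mm, r_ml,
p_ml, r_lm, p_lm).
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import ExpressionMatrix, log_normalized
from .network import LNC_MI, MI_M, CeRNANetwork

log = logging.getLogger(__name__)

TRIPLE_COLUMNS = [
    "cancer", "mRNA", "miRNA", "lncRNA",
    "r_mm", "p_mm", "r_ml", "p_ml", "r_lm", "p_lm",
]


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-test p on n-2 df.

    Requires n >= 3 and non-constant vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need n >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


_METHODS = {"pearson": pearson, "spearman": spearman}


def correlate_triples(
    subnetwork: CeRNANetwork,
    expression: Mapping[str, ExpressionMatrix],
    tumor_only: bool = True,
    method: str = "pearson",
) -> pd.DataFrame:
    """Three pairwise correlations for every lncRNA-miRNA-mRNA path.

    A path is a lnc_mi edge and a mi_m edge through the same miRNA.
    ``expression`` maps RNA class to its matrix; all three matrices must
    share at least 3 (tumor) samples.  A path whose gene is absent from
    its class matrix is skipped with a warning.
    """
    corr = _METHODS[method]
    cancer = next(iter(expression.values())).cancer if expression else ""
    logx = {}
    for rna_class, matrix in expression.items():
        frame = log_normalized(matrix)
        if tumor_only:
            frame = frame[matrix.condition_columns("tumor")]
        logx[rna_class] = frame
    shared = None
    for frame in logx.values():
        cols = set(frame.columns)
        shared = cols if shared is None else shared & cols
    shared = sorted(shared or ())
    if len(shared) < 3:
        raise ValueError(f"need >=3 shared samples across classes, have {len(shared)}")

    rows = []
    for mirna in subnetwork.nodes_of_class("miRNA"):
        lncs = sorted(subnetwork.neighbors_by_kind(mirna, LNC_MI))
        mrnas = sorted(subnetwork.neighbors_by_kind(mirna, MI_M))
        for lnc in lncs:
            for mrna in mrnas:
                try:
                    vm = logx["mRNA"].loc[mrna, shared].to_numpy()
                    vmi = logx["miRNA"].loc[mirna, shared].to_numpy()
                    vl = logx["lncRNA"].loc[lnc, shared].to_numpy()
                except KeyError as err:
                    log.warning("correlate_triples: gene %s absent; skipping %s/%s/%s",
                                err, lnc, mirna, mrna)
                    continue
                try:
                    r_mm, p_mm = corr(vm, vmi)
                    r_ml, p_ml = corr(vmi, vl)
                    r_lm, p_lm = corr(vm, vl)
                except ValueError as err:
                    log.warning("correlate_triples: %s for %s/%s/%s; skipped",
                                err, lnc, mirna, mrna)
                    continue
                rows.append(
                    {
                        "cancer": cancer, "mRNA": mrna, "miRNA": mirna, "lncRNA": lnc,
                        "r_mm": r_mm, "p_mm": p_mm, "r_ml": r_ml, "p_ml": p_ml,
                        "r_lm": r_lm, "p_lm": p_lm,
                    }
                )
    return pd.DataFrame(rows, columns=TRIPLE_COLUMNS)


def apply_axis_filter(triples: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Annotate each triple with the (-, -, +) verdict.

    verdict is true iff r_mm < 0, r_ml < 0, r_lm > 0 and all three
    p-values are strictly below alpha.  Passing records are sorted first;
    the full annotated table is returned.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    out = triples.copy()
    if len(out) == 0:
        out["verdict"] = pd.Series(dtype=bool)
        return out
    out["verdict"] = (
        (out["r_mm"] < 0) & (out["p_mm"] < alpha)
        & (out["r_ml"] < 0) & (out["p_ml"] < alpha)
        & (out["r_lm"] > 0) & (out["p_lm"] < alpha)
    )
    out = out.sort_values("verdict", ascending=False, kind="stable", ignore_index=True)
    log.info("apply_axis_filter: %d of %d triples pass at alpha=%g",
             int(out["verdict"].sum()), len(out), alpha)
    return out


def summarize_axes(axes: pd.DataFrame) -> pd.DataFrame:
    """Per-cancer tallies over the passing axes: axis count, distinct
    lncRNA/miRNA/mRNA counts, total distinct nodes, and distinct
    significant pair counts per pair type."""
    if "verdict" not in axes.columns:
        raise ValueError("run apply_axis_filter first")
    passing = axes[axes["verdict"]]
    rows = []
    for cancer, sub in passing.groupby("cancer", sort=True):
        n_lnc = sub["lncRNA"].nunique()
        n_mi = sub["miRNA"].nunique()
        n_m = sub["mRNA"].nunique()
        rows.append(
            {
                "cancer": cancer,
                "axes": len(sub),
                "lncRNAs": n_lnc,
                "miRNAs": n_mi,
                "mRNAs": n_m,
                "nodes": n_lnc + n_mi + n_m,
                "mi_m_pairs": sub[["miRNA", "mRNA"]].drop_duplicates().shape[0],
                "mi_lnc_pairs": sub[["miRNA", "lncRNA"]].drop_duplicates().shape[0],
                "lnc_m_pairs": sub[["lncRNA", "mRNA"]].drop_duplicates().shape[0],
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cancer", "axes", "lncRNAs", "miRNAs", "mRNAs", "nodes",
                 "mi_m_pairs", "mi_lnc_pairs", "lnc_m_pairs"],
    )


def read_correlation_table(path: str | Path) -> pd.DataFrame:
    """Read a pre-computed correlation TSV with the standard column layout
    (comment lines starting with '#' are ignored)."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in TRIPLE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"correlation table missing columns {missing}")
    return frame[TRIPLE_COLUMNS]
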