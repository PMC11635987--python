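"""Readers and writers for the pipeline's external formats.

All tables are TSV with a single header line.  Count matrices are genes x
samples with the gene id in the first column; interaction pair tables carry
the pair in the first two columns (plus named evidence columns for
miRNA-mRNA pairs); clinical tables are (sample, time, event).  Networks are
exported as Cytoscape SIF ("A interacts B") plus node- and edge-attribute
TSVs, and can be read back losslessly.  Gene sets use the GMT format.

Parsers fail loud: duplicate gene ids, non-integer or negative counts,
unannotated samples and invalid survival records are hard errors naming the
offender; nothing is silently dropped.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexpr import ExpressionMatrix
from .enrichment import GeneSetCollection
from .network import (
    EVIDENCE_COLUMNS,
    LNC_MI,
    MI_M,
    PAIR_COLUMNS,
    CeRNANetwork,
    InteractionTable,
)
from .prognosis import validate_survival

log = logging.getLogger(__name__)

SIF_INTERACTION = "interacts"

ANNOTATION_COLUMNS = ["sample", "condition", "cancer"]


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Sample annotation TSV: sample, condition (tumor/normal), cancer."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"annotation missing columns {missing}")
    dup = frame.duplicated(subset=["sample", "cancer"])
    if dup.any():
        raise ValueError(f"duplicate sample {frame.loc[dup, 'sample'].iloc[0]!r} in annotation")
    return frame[ANNOTATION_COLUMNS]


def read_count_matrix(
    path: str | Path,
    rna_class: str,
    annotation: pd.DataFrame,
    cancer: str,
) -> ExpressionMatrix:
    """Read a gene x sample count TSV into an :class:`ExpressionMatrix`.

    Every sample column must appear in the annotation for ``cancer``.
    Duplicate gene ids, non-integer or negative cells, and unannotated
    samples are hard errors naming the offender.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if not frame.index.is_unique:
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r} in {path}")
    values = frame.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"non-numeric counts in {path}")
    float_values = values.astype(float)
    bad = ~np.isfinite(float_values) | (float_values != np.floor(float_values))
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise ValueError(
            f"non-integer count at gene {frame.index[g]!r}, sample "
            f"{frame.columns[s]!r} in {path}"
        )
    if (float_values < 0).any():
        g, s = np.argwhere(float_values < 0)[0]
        raise ValueError(
            f"negative count at gene {frame.index[g]!r}, sample "
            f"{frame.columns[s]!r} in {path}"
        )
    frame = frame.astype(np.int64)
    ann = annotation[annotation["cancer"] == cancer].set_index("sample")
    unknown = [s for s in frame.columns if s not in ann.index]
    if unknown:
        raise ValueError(f"sample {unknown[0]!r} missing from annotation for {cancer}")
    conditions = ann["condition"].reindex(frame.columns)
    matrix = ExpressionMatrix(frame, rna_class, cancer, conditions)
    log.info("read_count_matrix %s: %d genes x %d samples (%s/%s)",
             path, *frame.shape, cancer, rna_class)
    return matrix


def write_count_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="gene")


def read_pair_table(path: str | Path, kind: str) -> InteractionTable:
    """Read a candidate-pair TSV.

    The first two columns are the pair (A, B); for ``mi_m`` the named
    evidence columns ``support_db_count`` and ``clip_exp_count`` are
    required.  Duplicate pairs are collapsed to one; extra columns on a
    ``lnc_mi`` table are ignored.  An empty file yields an empty table
    with a warning.
    """
    if kind not in PAIR_COLUMNS:
        raise ValueError(f"kind must be one of {sorted(PAIR_COLUMNS)}, got {kind!r}")
    frame = pd.read_csv(path, sep="\t")
    cols = PAIR_COLUMNS[kind]
    if len(frame.columns) < 2:
        raise ValueError(f"pair table {path} needs at least two columns")
    if len(frame) == 0:
        log.warning("read_pair_table %s: empty table", path)
        empty = pd.DataFrame(columns=cols + (EVIDENCE_COLUMNS if kind == MI_M else []))
        return InteractionTable(kind, empty)
    out = frame.rename(columns=dict(zip(frame.columns[:2], cols)))
    if kind == MI_M:
        missing = [c for c in EVIDENCE_COLUMNS if c not in out.columns]
        if missing:
            raise ValueError(f"mi_m table {path} missing evidence columns {missing}")
    table = InteractionTable(kind, out)
    dropped = len(frame) - len(table)
    if dropped:
        log.info("read_pair_table %s: collapsed %d duplicate pairs", path, dropped)
    log.info("read_pair_table %s: %d %s pairs", path, len(table), kind)
    return table


def write_pair_table(table: InteractionTable, path: str | Path) -> None:
    table.pairs.to_csv(path, sep="\t", index=False)


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Survival TSV (sample, time, event) with invariants enforced:
    time > 0, event in {0,1}, unique non-empty samples."""
    frame = pd.read_csv(path, sep="\t")
    records = validate_survival(frame)
    log.info("read_clinical %s: %d records, %d events",
             path, len(records), int(records['event'].sum()))
    return records


def write_clinical(records: pd.DataFrame, path: str | Path) -> None:
    validate_survival(records).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Network export (SIF + attribute tables)

def _fmt_cancers(cancers) -> str:
    return ",".join(sorted(cancers))


def write_network(network: CeRNANetwork, prefix: str | Path) -> dict[str, Path]:
    """Write ``<prefix>.sif`` plus ``<prefix>.nodes.tsv`` and
    ``<prefix>.edges.tsv``; an empty network yields an empty SIF and
    header-only tables."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    sif = prefix.with_suffix(prefix.suffix + ".sif")
    edges = sorted(network.edge_set())
    with open(sif, "w") as handle:
        for u, v, _ in edges:
            handle.write(f"{u}\t{SIF_INTERACTION}\t{v}\n")
    nodes_path = prefix.with_suffix(prefix.suffix + ".nodes.tsv")
    node_rows = [
        {
            "gene": n,
            "rna_class": d["rna_class"],
            "direction": d["direction"],
            "category": d["category"],
            "cancers": _fmt_cancers(d["cancers"]),
            "is_key": int(bool(d.get("is_key", False))),
        }
        for n, d in sorted(network.graph.nodes(data=True))
    ]
    pd.DataFrame(
        node_rows,
        columns=["gene", "rna_class", "direction", "category", "cancers", "is_key"],
    ).to_csv(nodes_path, sep="\t", index=False)
    edges_path = prefix.with_suffix(prefix.suffix + ".edges.tsv")
    edge_rows = [
        {
            "source": min(u, v),
            "target": max(u, v),
            "kind": d["kind"],
            "cancers": _fmt_cancers(d["cancers"]),
        }
        for u, v, d in network.graph.edges(data=True)
    ]
    edge_rows.sort(key=lambda r: (r["source"], r["target"]))
    pd.DataFrame(edge_rows, columns=["source", "target", "kind", "cancers"]).to_csv(
        edges_path, sep="\t", index=False
    )
    log.info("write_network %s: %d nodes, %d edges", prefix, len(node_rows), len(edge_rows))
    return {"sif": sif, "nodes": nodes_path, "edges": edges_path}


def read_network(prefix: str | Path, cancer_universe=()) -> CeRNANetwork:
    """Rebuild a network from its node- and edge-attribute tables."""
    prefix = Path(prefix)
    nodes = pd.read_csv(prefix.with_suffix(prefix.suffix + ".nodes.tsv"), sep="\t")
    edges = pd.read_csv(prefix.with_suffix(prefix.suffix + ".edges.tsv"), sep="\t")
    net = CeRNANetwork(cancer_universe)
    for _, row in nodes.iterrows():
        net.add_node(
            row["gene"], row["rna_class"], row["direction"], row["category"],
            str(row["cancers"]).split(",") if pd.notna(row["cancers"]) and row["cancers"] else (),
            is_key=bool(row.get("is_key", 0)),
        )
    for _, row in edges.iterrows():
        net.add_edge(
            row["source"], row["target"], row["kind"], str(row["cancers"]).split(","),
        )
    return net


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gmt(path: str | Path) -> list[tuple[str, str, frozenset[str]]]:
    """GMT: one set per line — name, description, then member genes."""
    sets = []
    with open(path) as handle:
        for lineno, line in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not line or (len(line) == 1 and not line[0].strip()):
                continue
            if len(line) < 3:
                raise ValueError(f"GMT line {lineno}: need name, description, >=1 gene")
            sets.append((line[0], line[1], frozenset(g for g in line[2:] if g)))
    log.info("read_gmt %s: %d sets", path, len(sets))
    return sets


def load_gene_set_collection(path: str | Path, universe) -> GeneSetCollection:
    return GeneSetCollection.from_sets(read_gmt(path), universe)
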