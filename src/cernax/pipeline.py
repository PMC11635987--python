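"""End-to-end orchestration of the mining workflow.

``run_pipeline`` takes per-cancer expression matrices, survival tables and
interaction tables (real or simulated) through the full chain:

1. differential expression per (cancer, RNA class) with signed calls;
2. cross-cancer categorization into shared / semi-shared / specific;
3. direction-constrained tripartite network assembly per category, with
   per-cancer portions of the semi-shared network;
4. univariate Cox screening of each cancer's network genes and key-gene
   calling by expression/prognosis concordance;
5. sub-ceRNA extraction around the key genes and correlation-based
   (-, -, +) axis mining.

``run_all`` wraps it with simulation and writes every artifact of the
workflow (DE tables, category and intersection tables, networks as
SIF + attribute TSVs, Cox tables, key-gene lists, axis tables) to an
output directory.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from . import axes as axes_mod
from . import cross_cancer, diffexpr, io, network, prognosis
from .config import RNA_CLASSES, PipelineConfig
from .simulate import SimulatedDataset, SimulationDesign, default_design, simulate_dataset

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineResult:
    de: dict[tuple[str, str], pd.DataFrame]  # (cancer, rna_class) -> DE table
    assignments: dict[str, list[cross_cancer.CategoryAssignment]]  # per class
    upset: dict[str, pd.DataFrame]  # per class
    shared: network.CeRNANetwork
    specific: dict[str, network.CeRNANetwork]  # per cancer
    semi_shared: network.CeRNANetwork
    semi_shared_portions: dict[str, network.CeRNANetwork]
    cox: dict[str, pd.DataFrame]  # per cancer, forest-plot-ready
    key_genes: dict[str, list[prognosis.KeyGeneCall]]
    sub_networks: dict[str, network.CeRNANetwork]
    triples: dict[str, pd.DataFrame]  # per cancer, verdict-annotated
    axis_summary: pd.DataFrame


def _combined_network_for_cancer(
    result_networks: list[network.CeRNANetwork], cancer_universe
) -> network.CeRNANetwork:
    """Union of the category networks relevant to one cancer (shared,
    cancer-specific, semi-shared portion); on node collisions the first
    network's attributes win."""
    combined = network.CeRNANetwork(cancer_universe)
    graphs = [n.graph for n in result_networks if n.graph.number_of_nodes()]
    if graphs:
        merged = graphs[0]
        for g in graphs[1:]:
            merged = nx.compose(g, merged)  # right side wins attribute conflicts
        combined.graph = merged.copy()
    combined.prune()
    return combined


def run_pipeline(dataset: SimulatedDataset, config: PipelineConfig) -> PipelineResult:
    cancers = [c for c in config.cancers if c in dataset.expression]
    if list(cancers) != list(config.cancers):
        raise ValueError(
            f"dataset covers {sorted(dataset.expression)}, config wants {list(config.cancers)}"
        )

    # 1. differential expression
    de: dict[tuple[str, str], pd.DataFrame] = {}
    for cancer in cancers:
        for rna_class in RNA_CLASSES:
            de[(cancer, rna_class)] = diffexpr.run_de(
                dataset.expression[cancer][rna_class], config
            )

    # 2. cross-cancer categorization
    assignments: dict[str, list[cross_cancer.CategoryAssignment]] = {}
    upset: dict[str, pd.DataFrame] = {}
    for rna_class in RNA_CLASSES:
        signed = {
            cancer: diffexpr.signed_sets(de[(cancer, rna_class)]) for cancer in cancers
        }
        profiles = cross_cancer.build_signatures(signed, cancers, rna_class)
        assignments[rna_class] = cross_cancer.categorize_all(profiles, len(cancers))
        upset[rna_class] = cross_cancer.upset_counts(profiles, cancers)

    # 3. networks
    mi_m = network.filter_mi_m_pairs(
        dataset.mi_m, config.min_support_db, config.min_clip
    )
    shared = network.assemble_network(
        assignments, dataset.lnc_mi, mi_m, "shared", cancer_universe=cancers
    )
    specific = {
        cancer: network.assemble_network(
            assignments, dataset.lnc_mi, mi_m, "specific", cancer_scope=cancer,
            cancer_universe=cancers,
        )
        for cancer in cancers
    }
    semi_shared = network.assemble_network(
        assignments, dataset.lnc_mi, mi_m, "semi_shared", cancer_universe=cancers
    )
    portions = {
        cancer: network.per_cancer_portion(semi_shared, cancer) for cancer in cancers
    }

    # 4. Cox screening and key genes per cancer
    cox: dict[str, pd.DataFrame] = {}
    key_genes: dict[str, list[prognosis.KeyGeneCall]] = {}
    sub_networks: dict[str, network.CeRNANetwork] = {}
    triples: dict[str, pd.DataFrame] = {}
    for cancer in cancers:
        combined = _combined_network_for_cancer(
            [shared, specific[cancer], portions[cancer]], cancers
        )
        survival = dataset.survival[cancer]
        log_expr = {
            rna_class: diffexpr.log_normalized(dataset.expression[cancer][rna_class])
            for rna_class in RNA_CLASSES
        }
        fits = []
        for gene in sorted(combined.graph.nodes):
            rna_class = combined.nodes[gene]["rna_class"]
            frame = log_expr[rna_class]
            if gene not in frame.index:
                log.warning("run_pipeline: %s absent from %s expression; skipped", gene, cancer)
                continue
            try:
                fits.append(prognosis.fit_cox(survival, frame.loc[gene], gene=gene))
            except (ValueError, RuntimeError) as err:
                log.warning("run_pipeline: Cox skipped for %s in %s: %s", gene, cancer, err)
        cox[cancer] = prognosis.fits_frame(fits)
        significant = [f for f in fits if f.pvalue < config.cox_alpha]
        directions: dict[str, str] = {}
        rna_classes: dict[str, str] = {}
        for rna_class in RNA_CLASSES:
            table = de[(cancer, rna_class)]
            for _, row in table.iterrows():
                directions[row["gene"]] = row["direction"]
                rna_classes[row["gene"]] = rna_class
        calls = prognosis.call_key_genes(
            significant, directions, rna_classes, validation_de=None,
            alpha=config.padj_alpha,
        )
        key_genes[cancer] = calls
        key_mrnas = {
            c.gene for c in calls if c.rna_class == "mRNA" and c.validation_consistent
        }
        key_lncrnas = {
            c.gene for c in calls if c.rna_class == "lncRNA" and c.validation_consistent
        }

        # 5. sub-ceRNA and axis mining
        sub = network.extract_sub_cerna(combined, key_mrnas, key_lncrnas)
        sub_networks[cancer] = sub
        if sub.graph.number_of_nodes():
            t = axes_mod.correlate_triples(
                sub, dataset.expression[cancer], tumor_only=True
            )
        else:
            t = pd.DataFrame(columns=axes_mod.TRIPLE_COLUMNS)
        triples[cancer] = axes_mod.apply_axis_filter(t, config.corr_alpha)

    non_empty = [t for t in triples.values() if len(t)]
    all_triples = pd.concat(non_empty, ignore_index=True) if non_empty else pd.DataFrame()
    axis_summary = (
        axes_mod.summarize_axes(all_triples) if len(all_triples) else pd.DataFrame()
    )
    return PipelineResult(
        de=de, assignments=assignments, upset=upset, shared=shared, specific=specific,
        semi_shared=semi_shared, semi_shared_portions=portions, cox=cox,
        key_genes=key_genes, sub_networks=sub_networks, triples=triples,
        axis_summary=axis_summary,
    )


def write_result(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (cancer, rna_class), table in result.de.items():
        table.to_csv(out / f"de_{cancer}_{rna_class}.tsv", sep="\t", index=False)
    for rna_class, assignment in result.assignments.items():
        cross_cancer.assignments_frame(assignment).to_csv(
            out / f"categories_{rna_class}.tsv", sep="\t", index=False
        )
        result.upset[rna_class].to_csv(
            out / f"upset_{rna_class}.tsv", sep="\t", index=False
        )
    io.write_network(result.shared, out / "network_shared")
    for cancer, net in result.specific.items():
        io.write_network(net, out / f"network_specific_{cancer}")
    io.write_network(result.semi_shared, out / "network_semi_shared")
    for cancer, net in result.semi_shared_portions.items():
        io.write_network(net, out / f"network_semi_shared_{cancer}")
    for cancer, table in result.cox.items():
        table.to_csv(out / f"cox_{cancer}.tsv", sep="\t", index=False)
    for cancer, calls in result.key_genes.items():
        prognosis.key_gene_frame(calls).to_csv(
            out / f"key_genes_{cancer}.tsv", sep="\t", index=False
        )
    for cancer, net in result.sub_networks.items():
        io.write_network(net, out / f"network_sub_{cancer}")
    for cancer, table in result.triples.items():
        table.to_csv(out / f"axes_{cancer}.tsv", sep="\t", index=False)
    result.axis_summary.to_csv(out / "axis_summary.tsv", sep="\t", index=False)


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotation_rows = []
    for cancer, by_class in dataset.expression.items():
        for rna_class, matrix in by_class.items():
            io.write_count_matrix(matrix, out / f"counts_{cancer}_{rna_class}.tsv")
        any_matrix = next(iter(by_class.values()))
        for sample, condition in any_matrix.conditions.items():
            annotation_rows.append(
                {"sample": sample, "condition": condition, "cancer": cancer}
            )
        io.write_clinical(dataset.survival[cancer], out / f"clinical_{cancer}.tsv")
    pd.DataFrame(annotation_rows).to_csv(out / "annotation.tsv", sep="\t", index=False)
    io.write_pair_table(dataset.lnc_mi, out / "pairs_lnc_mi.tsv")
    io.write_pair_table(dataset.mi_m, out / "pairs_mi_m.tsv")
    dataset.truth.manifest_frame().to_csv(out / "ground_truth.tsv", sep="\t", index=False)


def run_all(
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    design: SimulationDesign | None = None,
    seed: int = 0,
    write_inputs: bool = True,
) -> PipelineResult:
    """Simulate the default (or given) design, run the full pipeline and
    write every artifact under ``out_dir``."""
    config = config or PipelineConfig(seed=seed)
    design = design or default_design()
    dataset = simulate_dataset(design, seed)
    if write_inputs:
        write_dataset(dataset, Path(out_dir) / "inputs")
    result = run_pipeline(dataset, config)
    write_result(result, out_dir)
    return result
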