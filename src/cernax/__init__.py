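"""cernax: cross-cancer competing endogenous RNA (ceRNA) network mining.

Differential expression on count matrices, shared / semi-shared / specific
categorization of signed DE genes across a cancer panel, direction-
constrained tripartite lncRNA-miRNA-mRNA network assembly, univariate Cox
prognostic screening, and sign-constrained correlation mining of ceRNA
regulatory axes — with a synthetic-data generator providing fully
ground-truthed inputs.
"""

from .config import DEFAULT_CANCERS, RNA_CLASSES, PipelineConfig, load_config
from .diffexpr import (
    ExpressionMatrix,
    bh_adjust,
    call_directions,
    estimate_dispersion,
    log_normalized,
    normalized_counts,
    run_de,
    signed_sets,
    test_de,
    tmm_factors,
)
from .cross_cancer import (
    CategoryAssignment,
    DysregulationProfile,
    build_signatures,
    categorize,
    categorize_all,
    upset_counts,
)
from .network import (
    CeRNANetwork,
    InteractionTable,
    assemble_network,
    extract_sub_cerna,
    filter_mi_m_pairs,
    network_summary,
    per_cancer_portion,
)
from .prognosis import (
    CoxFit,
    KeyGeneCall,
    call_key_genes,
    fit_cox,
    screen_prognostic,
    validate_survival,
)
from .axes import (
    apply_axis_filter,
    correlate_triples,
    pearson,
    read_correlation_table,
    summarize_axes,
)
from .enrichment import GeneSetCollection, hypergeom_tail, ora
from .simulate import (
    AxisPlan,
    DEPlan,
    SimulationDesign,
    SurvivalPlan,
    default_design,
    simulate_dataset,
    simulate_survival,
)
from .pipeline import PipelineResult, run_all, run_pipeline

__version__ = "0.1.0"

from importlib import resources as _resources


def bundled_correlation_table():
    """Path to the packaged correlation table of reported candidate ceRNA
    axes in STAD, LIHC and COAD (TCGA tumor co-expression values)."""
    return _resources.files("cernax") / "data" / "cerna_axis_correlations.tsv"
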