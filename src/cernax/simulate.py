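"""Synthetic multi-cancer expression, interaction and survival data.

The generator emulates the statistical structure the pipeline assumes in
its real inputs, with a ground-truth manifest so every downstream stage is
testable without any download:

* **Counts** are negative binomial with variance mu + phi*mu^2 around
  log-normally distributed per-gene baselines; tumor means of planted DE
  genes are multiplied by 2^(log2 fold) in their configured cancer subset.
* **ceRNA axes** are induced by a latent factor: for each planted
  lncRNA/miRNA/mRNA triple and each tumor sample, u ~ Normal(0, 1) shifts
  the log2 means by +gamma_L*u (lncRNA), -gamma_m*u (miRNA) and
  +gamma_R*u (mRNA), producing the expected (-, -, +) correlation pattern
  without modelling titration kinetics.
* **Interaction tables** contain every planted-axis pair with evidence
  counts that pass the configured filter, plus decoy pairs whose evidence
  counts straddle the thresholds.
* **Survival** is exponential with hazard lambda0 * exp(beta * z) where z
  is the standardized expression of the planted prognostic gene, censored
  at a fixed horizon.

Randomness derives from a single root seed split hierarchically with
``numpy.random.SeedSequence`` spawn keys (stage -> cancer -> class ->
gene), so enlarging the design does not perturb existing draws.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_CANCERS, RNA_CLASSES
from .diffexpr import ExpressionMatrix
from .network import LNC_MI, MI_M, InteractionTable

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class DEPlan:
    gene: str
    cancers: tuple[str, ...]
    direction: str  # up | down
    log2fold: float

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be up/down, got {self.direction!r}")
        if not self.log2fold > 0:
            raise ValueError("log2fold must be strictly positive")


@dataclasses.dataclass(frozen=True)
class AxisPlan:
    lncrna: str
    mirna: str
    mrna: str
    gamma_l: float = 0.8
    gamma_m: float = 0.8
    gamma_r: float = 0.8
    cancers: tuple[str, ...] | None = None  # None = all cancers

    def __post_init__(self) -> None:
        for g in (self.gamma_l, self.gamma_m, self.gamma_r):
            if g < 0:
                raise ValueError("coupling strengths must be >= 0")


@dataclasses.dataclass(frozen=True)
class SurvivalPlan:
    gene: str
    cancer: str
    beta: float


@dataclasses.dataclass
class SimulationDesign:
    cancers: tuple[str, ...] = DEFAULT_CANCERS
    genes_per_class: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"lncRNA": 700, "miRNA": 300, "mRNA": 2000}
    )
    n_tumor: int = 100
    n_normal: int = 50
    baseline_mean: float = 100.0
    baseline_log2_sd: float = 2.0
    dispersion: float = 0.1
    de_plan: list[DEPlan] = dataclasses.field(default_factory=list)
    axis_plan: list[AxisPlan] = dataclasses.field(default_factory=list)
    decoy_pairs: int = 200
    min_support_db: int = 2
    min_clip: int = 1
    survival_plan: list[SurvivalPlan] = dataclasses.field(default_factory=list)
    baseline_hazard: float = 5e-4  # events per day
    censor_time: float = 1825.0  # days (5 years)

    def __post_init__(self) -> None:
        if self.n_tumor < 2 or self.n_normal < 2:
            raise ValueError("need >= 2 tumor and >= 2 normal samples")
        if not self.baseline_mean > 0 or self.dispersion < 0:
            raise ValueError("baseline_mean must be > 0 and dispersion >= 0")
        ids = self.gene_ids()
        class_of: dict[str, str] = {}
        for rna_class, genes in ids.items():
            for g in genes:
                class_of[g] = rna_class
        for axis in self.axis_plan:
            for gene, rna_class in (
                (axis.lncrna, "lncRNA"), (axis.mirna, "miRNA"), (axis.mrna, "mRNA")
            ):
                if class_of.get(gene) != rna_class:
                    raise ValueError(
                        f"axis member {gene!r} not among the generated {rna_class} genes"
                    )

    def gene_ids(self) -> dict[str, list[str]]:
        prefixes = {"lncRNA": "LNC", "miRNA": "MIR", "mRNA": "MRNA"}
        return {
            rna_class: [
                f"{prefixes[rna_class]}{i:04d}"
                for i in range(1, self.genes_per_class[rna_class] + 1)
            ]
            for rna_class in RNA_CLASSES
        }


@dataclasses.dataclass
class GroundTruth:
    """Planted truth of one simulated dataset, for recovery testing."""

    de: pd.DataFrame  # gene, rna_class, cancer, direction, log2fold
    axes: list[AxisPlan]
    decoy_triples: pd.DataFrame  # lncRNA, miRNA, mRNA, support_db_count, clip_exp_count
    survival: pd.DataFrame  # gene, cancer, beta

    def manifest_frame(self) -> pd.DataFrame:
        """Single-file manifest with a record_type discriminator column."""
        parts = []
        de = self.de.copy()
        de.insert(0, "record_type", "de")
        parts.append(de)
        axes = pd.DataFrame(
            [
                {
                    "record_type": "axis", "lncRNA": a.lncrna, "miRNA": a.mirna,
                    "mRNA": a.mrna, "gamma_l": a.gamma_l, "gamma_m": a.gamma_m,
                    "gamma_r": a.gamma_r,
                    "cancers": ",".join(a.cancers) if a.cancers else "all",
                }
                for a in self.axes
            ]
        )
        parts.append(axes)
        decoys = self.decoy_triples.copy()
        decoys.insert(0, "record_type", "decoy_triple")
        parts.append(decoys)
        surv = self.survival.copy()
        surv.insert(0, "record_type", "survival")
        parts.append(surv)
        return pd.concat(parts, ignore_index=True, sort=False)


@dataclasses.dataclass
class SimulatedDataset:
    expression: dict[str, dict[str, ExpressionMatrix]]  # cancer -> class -> matrix
    survival: dict[str, pd.DataFrame]  # cancer -> (sample, time, event)
    lnc_mi: InteractionTable
    mi_m: InteractionTable
    truth: GroundTruth


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    mean = np.maximum(mean, 1e-12)
    if phi <= 0:
        return rng.poisson(mean)
    size = 1.0 / phi
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_dataset(design: SimulationDesign, seed: int) -> SimulatedDataset:
    """Draw the full multi-cancer dataset described by ``design``.

    Identical (design, seed) pairs reproduce byte-identical output.
    """
    ids = design.gene_ids()
    n_t, n_n = design.n_tumor, design.n_normal

    # stage 0: per-gene baselines, shared across cancers
    baselines: dict[str, np.ndarray] = {}
    for ci, rna_class in enumerate(RNA_CLASSES):
        rng = _rng(seed, 0, ci)
        log2_base = rng.normal(
            np.log2(design.baseline_mean), design.baseline_log2_sd,
            size=len(ids[rna_class]),
        )
        baselines[rna_class] = 2.0 ** log2_base

    de_by_gene_cancer: dict[tuple[str, str], DEPlan] = {}
    for plan in design.de_plan:
        for cancer in plan.cancers:
            de_by_gene_cancer[(plan.gene, cancer)] = plan
    axis_shift: dict[tuple[str, str], tuple[int, float]] = {}  # (cancer, gene) -> (axis idx, signed gamma)
    for ai, axis in enumerate(design.axis_plan):
        for cancer in axis.cancers or design.cancers:
            axis_shift[(cancer, axis.lncrna)] = (ai, +axis.gamma_l)
            axis_shift[(cancer, axis.mirna)] = (ai, -axis.gamma_m)
            axis_shift[(cancer, axis.mrna)] = (ai, +axis.gamma_r)

    expression: dict[str, dict[str, ExpressionMatrix]] = {}
    for cancer_idx, cancer in enumerate(design.cancers):
        # stage 1: latent axis factors per tumor sample
        u = _rng(seed, 1, cancer_idx).normal(size=(max(len(design.axis_plan), 1), n_t))
        samples = [f"{cancer}_T{i:03d}" for i in range(1, n_t + 1)] + [
            f"{cancer}_N{i:03d}" for i in range(1, n_n + 1)
        ]
        conditions = pd.Series(["tumor"] * n_t + ["normal"] * n_n, index=samples)
        expression[cancer] = {}
        for class_idx, rna_class in enumerate(RNA_CLASSES):
            genes = ids[rna_class]
            counts = np.empty((len(genes), n_t + n_n), dtype=np.int64)
            for gene_idx, gene in enumerate(genes):
                mean = np.full(n_t + n_n, baselines[rna_class][gene_idx])
                plan = de_by_gene_cancer.get((gene, cancer))
                if plan is not None:
                    fold = plan.log2fold if plan.direction == "up" else -plan.log2fold
                    mean[:n_t] *= 2.0 ** fold
                shift = axis_shift.get((cancer, gene))
                if shift is not None:
                    ai, gamma = shift
                    mean[:n_t] = mean[:n_t] * 2.0 ** (gamma * u[ai])
                # stage 2: per-gene count stream
                rng = _rng(seed, 2, cancer_idx, class_idx, gene_idx)
                counts[gene_idx] = _nb_draw(rng, mean, design.dispersion)
            frame = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples)
            expression[cancer][rna_class] = ExpressionMatrix(
                frame, rna_class, cancer, conditions
            )
        log.info("simulate_dataset: %s counts done (%d+%d samples)", cancer, n_t, n_n)

    lnc_mi, mi_m, decoy_triples = _simulate_pairs(design, seed)
    survival = _simulate_survival_tables(design, seed, expression)

    de_rows = [
        {
            "gene": p.gene,
            "rna_class": next(c for c in RNA_CLASSES if p.gene in set(ids[c])),
            "cancer": cancer, "direction": p.direction, "log2fold": p.log2fold,
        }
        for p in design.de_plan for cancer in p.cancers
    ]
    truth = GroundTruth(
        de=pd.DataFrame(de_rows, columns=["gene", "rna_class", "cancer", "direction", "log2fold"]),
        axes=list(design.axis_plan),
        decoy_triples=decoy_triples,
        survival=pd.DataFrame(
            [{"gene": s.gene, "cancer": s.cancer, "beta": s.beta} for s in design.survival_plan],
            columns=["gene", "cancer", "beta"],
        ),
    )
    return SimulatedDataset(expression, survival, lnc_mi, mi_m, truth)


def _simulate_pairs(design: SimulationDesign, seed: int):
    """Planted-axis pairs (evidence always passing) plus decoy triples whose
    evidence straddles the filter thresholds."""
    rng = _rng(seed, 3)
    lnc_mi_rows, mi_m_rows, decoy_rows = [], [], []
    for axis in design.axis_plan:
        lnc_mi_rows.append({"lncRNA": axis.lncrna, "miRNA": axis.mirna})
        mi_m_rows.append(
            {
                "miRNA": axis.mirna, "mRNA": axis.mrna,
                "support_db_count": int(rng.integers(design.min_support_db, 8)),
                "clip_exp_count": int(rng.integers(design.min_clip, 11)),
            }
        )
    ids = design.gene_ids()
    axis_genes = {g for a in design.axis_plan for g in (a.lncrna, a.mirna, a.mrna)}
    pool = {
        rna_class: [g for g in ids[rna_class] if g not in axis_genes]
        for rna_class in RNA_CLASSES
    }
    n_triples = design.decoy_pairs // 2
    for _ in range(n_triples):
        lnc = pool["lncRNA"][int(rng.integers(len(pool["lncRNA"])))]
        mi = pool["miRNA"][int(rng.integers(len(pool["miRNA"])))]
        m = pool["mRNA"][int(rng.integers(len(pool["mRNA"])))]
        support = int(rng.integers(0, 8))  # straddles the >= min_support_db filter
        clip = int(rng.integers(0, 6))  # straddles the >= min_clip filter
        lnc_mi_rows.append({"lncRNA": lnc, "miRNA": mi})
        mi_m_rows.append(
            {"miRNA": mi, "mRNA": m, "support_db_count": support, "clip_exp_count": clip}
        )
        decoy_rows.append(
            {
                "lncRNA": lnc, "miRNA": mi, "mRNA": m,
                "support_db_count": support, "clip_exp_count": clip,
            }
        )
    lnc_mi = InteractionTable(LNC_MI, pd.DataFrame(lnc_mi_rows, columns=["lncRNA", "miRNA"]))
    mi_m = InteractionTable(
        MI_M,
        pd.DataFrame(
            mi_m_rows, columns=["miRNA", "mRNA", "support_db_count", "clip_exp_count"]
        ),
    )
    decoys = pd.DataFrame(
        decoy_rows, columns=["lncRNA", "miRNA", "mRNA", "support_db_count", "clip_exp_count"]
    )
    return lnc_mi, mi_m, decoys


def _standardize(values: np.ndarray) -> np.ndarray:
    sd = values.std(ddof=0)
    if sd == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def _simulate_survival_tables(
    design: SimulationDesign, seed: int,
    expression: dict[str, dict[str, ExpressionMatrix]],
) -> dict[str, pd.DataFrame]:
    """Exponential survival for the tumor samples of each cancer, with the
    log hazard shifted by the planted coefficients on standardized
    log2(count+1) expression."""
    ids = design.gene_ids()
    class_of = {g: c for c in RNA_CLASSES for g in ids[c]}
    out: dict[str, pd.DataFrame] = {}
    for cancer_idx, cancer in enumerate(design.cancers):
        rng = _rng(seed, 5, cancer_idx)
        any_matrix = expression[cancer]["mRNA"]
        tumor_samples = any_matrix.condition_columns("tumor")
        log_rate = np.full(len(tumor_samples), np.log(design.baseline_hazard))
        for plan in design.survival_plan:
            if plan.cancer != cancer:
                continue
            matrix = expression[cancer][class_of[plan.gene]]
            expr = np.log2(matrix.counts.loc[plan.gene, tumor_samples].to_numpy() + 1.0)
            log_rate = log_rate + plan.beta * _standardize(expr)
        t_event = rng.exponential(1.0 / np.exp(log_rate))
        time = np.minimum(t_event, design.censor_time)
        event = (t_event <= design.censor_time).astype(int)
        out[cancer] = pd.DataFrame(
            {"sample": tumor_samples, "time": time, "event": event}
        )
    return out


def simulate_survival(
    expr_values: np.ndarray | pd.Series,
    beta: float,
    lambda0: float,
    censor_time: float,
    seed: int,
) -> pd.DataFrame:
    """Exponential survival for one covariate.

    T ~ Exponential(lambda0 * exp(beta * z)) with z the standardized
    expression; observed time = min(T, censor_time), event = 1 iff
    T <= censor_time.
    """
    if not lambda0 > 0 or not censor_time > 0:
        raise ValueError("lambda0 and censor_time must be strictly positive")
    if isinstance(expr_values, pd.Series):
        samples = list(expr_values.index)
        values = expr_values.to_numpy(dtype=float)
    else:
        values = np.asarray(expr_values, dtype=float)
        samples = [f"S{i:04d}" for i in range(1, len(values) + 1)]
    if len(values) < 2:
        raise ValueError("need at least 2 samples")
    z = _standardize(values)
    rng = np.random.default_rng(seed)
    rate = lambda0 * np.exp(beta * z)
    t_event = rng.exponential(1.0 / rate)
    time = np.minimum(t_event, censor_time)
    event = (t_event <= censor_time).astype(int)
    return pd.DataFrame({"sample": samples, "time": time, "event": event})


def default_design(
    genes_per_class: Mapping[str, int] | None = None,
    n_axes: int = 20,
    decoy_pairs: int = 200,
    n_tumor: int = 100,
    n_normal: int = 50,
    gamma: float = 0.8,
    de_log2fold: float = 2.0,
    dispersion: float = 0.1,
    n_extra_de: int = 5,
    survival_beta: float = 0.5,
) -> SimulationDesign:
    """The study-conditions default: a 4-cancer panel with planted shared
    ceRNA axes, extra specific/semi-shared DE genes, decoy pairs, and
    prognostic effects on the axis mRNAs and lncRNAs.

    Axis members are planted DE with the ceRNA sign pattern (lncRNA up,
    miRNA down, mRNA up) in every cancer, so the axes live in the shared
    network; axis mRNAs carry a hazard coefficient of ``survival_beta``
    (lncRNAs 0.8 * that) so they survive the prognostic screen.
    """
    if genes_per_class is None:
        genes_per_class = {"lncRNA": 700, "miRNA": 300, "mRNA": 2000}
    design = SimulationDesign(
        genes_per_class=dict(genes_per_class),
        n_tumor=n_tumor,
        n_normal=n_normal,
        dispersion=dispersion,
        decoy_pairs=decoy_pairs,
    )
    ids = design.gene_ids()
    cancers = design.cancers
    if n_axes > min(len(v) for v in ids.values()):
        raise ValueError("n_axes exceeds the per-class gene count")
    de_plan, axis_plan, survival_plan = [], [], []
    for i in range(n_axes):
        lnc, mi, m = ids["lncRNA"][i], ids["miRNA"][i], ids["mRNA"][i]
        axis_plan.append(AxisPlan(lnc, mi, m, gamma, gamma, gamma))
        de_plan.append(DEPlan(lnc, cancers, "up", de_log2fold))
        de_plan.append(DEPlan(mi, cancers, "down", de_log2fold))
        de_plan.append(DEPlan(m, cancers, "up", de_log2fold))
        for cancer in cancers:
            survival_plan.append(SurvivalPlan(m, cancer, survival_beta))
            survival_plan.append(SurvivalPlan(lnc, cancer, 0.8 * survival_beta))
    # extra DE genes exercising the specific and semi-shared categories
    for rna_class in RNA_CLASSES:
        genes = ids[rna_class]
        base = n_axes
        for j in range(n_extra_de):
            cancer = cancers[j % len(cancers)]
            de_plan.append(DEPlan(genes[base + j], (cancer,), "up", de_log2fold))
        for j in range(n_extra_de):
            pair = (cancers[j % len(cancers)], cancers[(j + 1) % len(cancers)])
            de_plan.append(DEPlan(genes[base + n_extra_de + j], pair, "down", de_log2fold))
    design.de_plan = de_plan
    design.axis_plan = axis_plan
    design.survival_plan = survival_plan
    design.__post_init__()  # re-validate axis membership
    return design
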