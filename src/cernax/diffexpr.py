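"""Per-cancer, per-RNA-class differential expression on count data.

The engine is an explicit approximation of the classic count-based DE
workflow for two-group comparisons:

* **TMM normalization** — trimmed mean of M-values scaling factors between
  libraries (reference sample chosen by 75th-percentile CPM; 30% two-sided
  trim on M, 5% on A; inverse-asymptotic-variance weights; factors rescaled
  to geometric mean 1).
* **NB dispersion** — a per-gene method-of-moments estimate of the
  negative-binomial dispersion phi (variance = mu + phi*mu^2) computed within
  conditions on normalized counts, shrunk toward the across-gene median.
* **NB likelihood-ratio test** — group-means model vs pooled-mean model with
  the dispersion held fixed at its estimate, chi-square with 1 df.
* **BH adjustment** within each (cancer, RNA class) stratum and signed
  up/down/ns calls against the configured |log2FC| threshold and adjusted-p
  cutoff.

The engine consumes an :class:`ExpressionMatrix` and emits a plain
DataFrame of per-gene records, so externally produced DE tables with the
same columns can be substituted anywhere downstream.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import special, stats

from .config import RNA_CLASSES, PipelineConfig

log = logging.getLogger(__name__)

TUMOR = "tumor"
NORMAL = "normal"

DISPERSION_FLOOR = 1e-8

DE_COLUMNS = ["gene", "rna_class", "cancer", "log2fc", "pvalue", "padj", "direction"]


@dataclasses.dataclass
class ExpressionMatrix:
    """Gene-level counts for one RNA class in one cancer.

    ``counts`` is genes x samples with unique gene ids as the index;
    ``conditions`` maps each sample column to ``"tumor"`` or ``"normal"``.
    """

    counts: pd.DataFrame
    rna_class: str
    cancer: str
    conditions: pd.Series

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(f"rna_class must be one of {RNA_CLASSES}, got {self.rna_class!r}")
        if not self.counts.index.is_unique:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        self.conditions = self.conditions.reindex(self.counts.columns)
        if self.conditions.isna().any():
            missing = self.conditions.index[self.conditions.isna()][0]
            raise ValueError(f"sample {missing!r} has no condition annotation")
        bad = set(self.conditions.unique()) - {TUMOR, NORMAL}
        if bad:
            raise ValueError(f"conditions must be tumor/normal, got {sorted(bad)}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def condition_columns(self, condition: str) -> list[str]:
        return list(self.conditions.index[self.conditions == condition])

    def require_two_per_condition(self) -> None:
        for condition in (TUMOR, NORMAL):
            n = int((self.conditions == condition).sum())
            if n < 2:
                raise ValueError(
                    f"{self.cancer}/{self.rna_class}: need >=2 {condition} samples, have {n}"
                )


# ---------------------------------------------------------------------------
# TMM normalization

def _tmm_pair(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float) -> float:
    """log2 TMM factor of one observation library against the reference."""
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return 0.0
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    po, pr = o / lib_obs, r / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # asymptotic variance of M (delta method on binomial proportions); the
    # proportion scale makes the weights — hence the factors — invariant to
    # a pure depth change of either library
    w = (1.0 - po) / po + (1.0 - pr) / pr
    w = np.maximum(w, 1e-12)  # a gene holding an entire library has zero variance
    n = m.size
    lo_m, hi_m = np.floor(n * 0.30) + 1, n - np.floor(n * 0.30)
    lo_a, hi_a = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
    rank_m = stats.rankdata(m, method="ordinal")
    rank_a = stats.rankdata(a, method="ordinal")
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 0.0
    return float(np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2]))


def tmm_factors(matrix: ExpressionMatrix) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The reference is the sample whose 75th-percentile CPM is closest to the
    mean 75th percentile across samples.  A sample with zero total count is
    a hard error.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = matrix.samples[np.argmax(lib == 0)]
        raise ValueError(f"sample {bad!r} has zero total count")
    p75 = np.array([np.percentile(counts[:, j] / lib[j] * 1e6, 75) for j in range(len(lib))])
    ref_idx = int(np.argmin(np.abs(p75 - p75.mean())))
    ref, lib_ref = counts[:, ref_idx], lib[ref_idx]
    logf = np.array(
        [_tmm_pair(counts[:, j], ref, lib[j], lib_ref) for j in range(counts.shape[1])]
    )
    factors = 2.0 ** (logf - logf.mean())  # geometric mean 1
    return pd.Series(factors, index=matrix.samples, name="tmm_factor")


def effective_library_sizes(matrix: ExpressionMatrix, factors: pd.Series) -> pd.Series:
    return matrix.counts.sum(axis=0) * factors


def normalized_counts(matrix: ExpressionMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts rescaled to a common effective library size (its mean)."""
    if factors is None:
        factors = tmm_factors(matrix)
    eff = effective_library_sizes(matrix, factors)
    return matrix.counts / eff * eff.mean()


def log_normalized(matrix: ExpressionMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """log2(normalized count + 1), the expression scale used for Cox
    covariates and correlation analysis."""
    return np.log2(normalized_counts(matrix, factors) + 1.0)


# ---------------------------------------------------------------------------
# Dispersion

def estimate_dispersion(
    matrix: ExpressionMatrix,
    factors: pd.Series,
    shrink_weight: float = 0.5,
) -> pd.Series:
    """Per-gene NB dispersion by the method of moments, with shrinkage.

    phi_hat = max(0, (s^2 - mu)/mu^2) on normalized counts, pooled across
    the two conditions (weighted by degrees of freedom so a true expression
    difference between groups does not inflate the estimate), then shrunk
    toward the across-gene median with weight ``shrink_weight`` and floored
    at 1e-8.
    """
    if not 0.0 <= shrink_weight <= 1.0:
        raise ValueError("shrink_weight must lie in [0, 1]")
    norm = normalized_counts(matrix, factors)
    num = np.zeros(norm.shape[0])
    den = 0.0
    for condition in (TUMOR, NORMAL):
        cols = matrix.condition_columns(condition)
        if len(cols) < 2:
            continue
        sub = norm[cols].to_numpy()
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_c = np.where(mu > 0, (var - mu) / np.maximum(mu, 1e-300) ** 2, 0.0)
        num += (len(cols) - 1) * np.maximum(phi_c, 0.0)
        den += len(cols) - 1
    phi = num / max(den, 1.0)
    median = float(np.median(phi))
    shrunk = (1.0 - shrink_weight) * phi + shrink_weight * median
    return pd.Series(np.maximum(shrunk, DISPERSION_FLOOR), index=matrix.genes, name="dispersion")


# ---------------------------------------------------------------------------
# NB likelihood-ratio test

def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row sums of the NB log-likelihood; alpha = 1/phi, column vector."""
    mu = np.maximum(mu, 1e-300)
    return np.sum(
        special.gammaln(y + alpha)
        - special.gammaln(alpha)
        - special.gammaln(y + 1.0)
        + alpha * np.log(alpha / (alpha + mu))
        + y * np.log(mu / (alpha + mu)),
        axis=1,
    )


def _fit_group_mean(y: np.ndarray, s: np.ndarray, alpha: np.ndarray, n_iter: int = 50) -> np.ndarray:
    """MLE of the per-gene mean rate q (mu_ij = s_j * q_g) with fixed
    dispersion, by Newton iterations on beta = log q. Vectorized over genes."""
    total = y.sum(axis=1)
    beta = np.log((total + 0.5) / s.sum())
    for _ in range(n_iter):
        mu = s[None, :] * np.exp(beta)[:, None]
        score = np.sum(alpha * (y - mu) / (mu + alpha), axis=1)
        info = np.sum(alpha * mu / (mu + alpha), axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        beta = np.clip(beta + step, -60.0, 60.0)
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def test_de(
    matrix: ExpressionMatrix,
    factors: pd.Series,
    dispersions: pd.Series,
) -> pd.DataFrame:
    """Per-gene NB likelihood-ratio test of tumor vs normal.

    Returns a DataFrame with columns ``gene, rna_class, cancer, log2fc,
    pvalue, padj, direction`` (direction is a ``"ns"`` placeholder until
    :func:`call_directions` applies the thresholds).  log2fc is the log2
    ratio of normalized tumor to normal group means with a 0.5/n-bar
    pseudo-count; padj is BH within this (cancer, class) stratum.
    """
    matrix.require_two_per_condition()
    y = matrix.counts.to_numpy(dtype=float)
    s = effective_library_sizes(matrix, factors).to_numpy()
    phi = dispersions.reindex(matrix.genes).to_numpy()
    alpha = (1.0 / np.maximum(phi, DISPERSION_FLOOR))[:, None]

    is_tumor = (matrix.conditions == TUMOR).to_numpy()
    groups = {"all": np.ones_like(is_tumor), TUMOR: is_tumor, NORMAL: ~is_tumor}
    loglik: dict[str, np.ndarray] = {}
    for name, mask in groups.items():
        beta = _fit_group_mean(y[:, mask], s[mask], alpha)
        mu = s[mask][None, :] * np.exp(beta)[:, None]
        loglik[name] = _nb_loglik(y[:, mask], mu, alpha)
    lrt = 2.0 * (loglik[TUMOR] + loglik[NORMAL] - loglik["all"])
    pvalue = stats.chi2.sf(np.maximum(lrt, 0.0), df=1)

    norm = normalized_counts(matrix, factors)
    mu_t = norm.loc[:, is_tumor].mean(axis=1).to_numpy()
    mu_n = norm.loc[:, ~is_tumor].mean(axis=1).to_numpy()
    n_bar = 0.5 * (is_tumor.sum() + (~is_tumor).sum())
    pseudo = 0.5 / n_bar
    log2fc = np.log2((mu_t + pseudo) / (mu_n + pseudo))

    out = pd.DataFrame(
        {
            "gene": matrix.genes,
            "rna_class": matrix.rna_class,
            "cancer": matrix.cancer,
            "log2fc": log2fc,
            "pvalue": pvalue,
            "padj": bh_adjust(pvalue),
            "direction": "ns",
        }
    ).reset_index(drop=True)
    log.info(
        "test_de %s/%s: %d genes, %d samples", matrix.cancer, matrix.rna_class,
        len(out), len(matrix.samples),
    )
    return out


def bh_adjust(pvalues: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    padj_(i) = min_{j >= i} min(1, m * p_(j) / j) on the ascending order
    statistics, mapped back to the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted
    return out


def call_directions(records: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Assign up/down/ns against the cancer-specific |log2FC| threshold and
    the global adjusted-p cutoff; comparisons are strict (>, <)."""
    out = records.copy()
    tau = out["cancer"].map(lambda c: config.lfc_for(c))
    significant = out["padj"] < config.padj_alpha
    out["direction"] = "ns"
    out.loc[significant & (out["log2fc"] > tau), "direction"] = "up"
    out.loc[significant & (out["log2fc"] < -tau), "direction"] = "down"
    counts = out["direction"].value_counts()
    log.info(
        "call_directions: %d up, %d down of %d (alpha=%g)",
        counts.get("up", 0), counts.get("down", 0), len(out), config.padj_alpha,
    )
    return out


def signed_sets(records: pd.DataFrame) -> dict[str, set[str]]:
    """Disjoint up/down gene sets from direction-called records."""
    return {
        "up": set(records.loc[records["direction"] == "up", "gene"]),
        "down": set(records.loc[records["direction"] == "down", "gene"]),
    }


def run_de(matrix: ExpressionMatrix, config: PipelineConfig) -> pd.DataFrame:
    """TMM -> dispersion -> LRT -> direction calls for one matrix."""
    factors = tmm_factors(matrix)
    dispersions = estimate_dispersion(matrix, factors)
    return call_directions(test_de(matrix, factors, dispersions), config)
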