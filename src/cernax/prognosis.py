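"""Univariate Cox screening and key-gene calling.

Each network node gene is screened with a univariate Cox proportional
hazards model on the standardized log2 expression of tumor samples
(log hazard ratio beta per 1 SD).  The partial likelihood uses Breslow
tie handling and is maximized by Newton-Raphson; the standard error comes
from the observed information.  Genes with p < alpha (no multiplicity
adjustment) are prognostic; key genes concordantly pair expression
direction with prognosis — up-regulated with HR > 1 (oncogene candidate)
or down-regulated with HR < 1 (suppressor candidate) — and can be
re-screened against a second, independent DE table for consistency
(miRNAs skip that validation).
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

SURVIVAL_COLUMNS = ["sample", "time", "event"]


def validate_survival(records: pd.DataFrame) -> pd.DataFrame:
    """Check survival-table invariants: unique samples, time > 0,
    event in {0, 1}; at least one record."""
    missing = [c for c in SURVIVAL_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"survival table missing columns {missing}")
    if len(records) == 0:
        raise ValueError("no survival records")
    if records["sample"].duplicated().any():
        dup = records.loc[records["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"duplicate sample {dup!r} in survival table")
    bad_time = records["time"] <= 0
    if bad_time.any():
        raise ValueError(
            f"non-positive time for sample {records.loc[bad_time, 'sample'].iloc[0]!r}"
        )
    bad_event = ~records["event"].isin([0, 1])
    if bad_event.any():
        raise ValueError(
            f"event not in {{0,1}} for sample {records.loc[bad_event, 'sample'].iloc[0]!r}"
        )
    out = records[SURVIVAL_COLUMNS].copy()
    out["time"] = out["time"].astype(float)
    out["event"] = out["event"].astype(int)
    return out


@dataclasses.dataclass(frozen=True)
class CoxFit:
    gene: str
    beta: float  # log hazard ratio per 1 SD of the covariate
    hr: float
    se: float
    z: float
    pvalue: float
    n: int
    n_events: int

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - 1.959963984540054 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + 1.959963984540054 * self.se))


def breslow_loglik(beta: float, time: np.ndarray, event: np.ndarray, x: np.ndarray) -> float:
    """Breslow log partial likelihood at a single beta (used directly by the
    brute-force oracle in tests; the fitter shares its risk-set layout)."""
    eta = beta * x
    order = np.argsort(-time, kind="stable")  # descending: risk set grows
    t, e, et = time[order], event[order], np.exp(eta[order])
    cum = np.cumsum(et)
    ll = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        events_here = [k for k in range(i, j + 1) if e[k] == 1]
        if events_here:
            s0 = cum[j]
            ll += float(beta * np.sum(x[order][events_here]) - len(events_here) * np.log(s0))
        i = j + 1
    return ll


def _risk_sums(beta: float, time: np.ndarray, event: np.ndarray, x: np.ndarray):
    """Per distinct event time: d, sum of x over events, S0, S1, S2 over the
    risk set (samples with time >= t)."""
    order = np.argsort(-time, kind="stable")
    t, e, xv = time[order], event[order], x[order]
    w = np.exp(beta * xv)
    c0 = np.cumsum(w)
    c1 = np.cumsum(w * xv)
    c2 = np.cumsum(w * xv * xv)
    out = []
    i, n = 0, len(t)
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        ev = [k for k in range(i, j + 1) if e[k] == 1]
        if ev:
            out.append((len(ev), float(np.sum(xv[ev])), float(c0[j]), float(c1[j]), float(c2[j])))
        i = j + 1
    return out


def fit_cox(
    survival: pd.DataFrame,
    covariate: pd.Series,
    gene: str = "",
    max_iter: int = 50,
    tol: float = 1e-8,
    dichotomize: bool = False,
) -> CoxFit:
    """Univariate Cox fit with Breslow ties by Newton-Raphson.

    The covariate is standardized (z-score, population SD) over the included
    samples, so beta is the log hazard ratio per 1 SD.  With
    ``dichotomize=True`` the covariate is first median-split into a
    high/low indicator (sensitivity analysis).  Raises on a constant
    covariate, zero events, fewer than 2 matched samples, or
    non-convergence.
    """
    records = validate_survival(survival)
    merged = records.merge(
        covariate.rename("x"), left_on="sample", right_index=True, how="inner"
    )
    if len(merged) < 2:
        raise ValueError(f"gene {gene!r}: fewer than 2 samples with covariate values")
    time = merged["time"].to_numpy()
    event = merged["event"].to_numpy()
    x = merged["x"].to_numpy(dtype=float)
    if dichotomize:
        x = (x > np.median(x)).astype(float)
    if event.sum() == 0:
        raise ValueError(f"gene {gene!r}: zero events")
    sd = x.std(ddof=0)  # population SD: replicating every record leaves z unchanged
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"gene {gene!r}: degenerate covariate")
    z = (x - x.mean()) / sd

    beta = 0.0
    info = np.nan
    trace = []
    for iteration in range(max_iter):
        score = 0.0
        info = 0.0
        for d, sx, s0, s1, s2 in _risk_sums(beta, time, event, z):
            score += sx - d * s1 / s0
            info += d * (s2 / s0 - (s1 / s0) ** 2)
        if info <= 0:
            # flat partial likelihood (constant covariate within every risk
            # set): no information about beta
            if abs(score) < 1e-8:
                raise ValueError(f"gene {gene!r}: degenerate covariate")
            raise RuntimeError(f"gene {gene!r}: non-positive information at beta={beta}")
        step = score / info
        # guard against overshoot on near-separated data
        step = float(np.clip(step, -2.0, 2.0))
        beta += step
        trace.append((iteration, beta, score))
        if abs(step) < tol:
            break
    else:
        raise RuntimeError(f"gene {gene!r}: Cox Newton did not converge; trace={trace}")
    se = float(1.0 / np.sqrt(info))
    zstat = beta / se
    pvalue = float(2.0 * stats.norm.sf(abs(zstat)))
    return CoxFit(
        gene=gene, beta=float(beta), hr=float(np.exp(beta)), se=se, z=float(zstat),
        pvalue=pvalue, n=len(merged), n_events=int(event.sum()),
    )


def fits_frame(fits: Sequence[CoxFit]) -> pd.DataFrame:
    """Forest-plot-ready table: gene, hr, ci_low, ci_high, pvalue (+ extras)."""
    return pd.DataFrame(
        [
            {
                "gene": f.gene, "hr": f.hr, "ci_low": f.ci_low, "ci_high": f.ci_high,
                "pvalue": f.pvalue, "beta": f.beta, "se": f.se, "n": f.n,
                "n_events": f.n_events,
            }
            for f in fits
        ],
        columns=["gene", "hr", "ci_low", "ci_high", "pvalue", "beta", "se", "n", "n_events"],
    )


def screen_prognostic(fits: Sequence[CoxFit], alpha: float) -> set[str]:
    """Genes with raw Cox p strictly below alpha (no FDR adjustment)."""
    kept = {f.gene for f in fits if f.pvalue < alpha}
    log.info("screen_prognostic: %d of %d genes at p<%g", len(kept), len(fits), alpha)
    return kept


@dataclasses.dataclass(frozen=True)
class KeyGeneCall:
    gene: str
    rna_class: str
    direction: str  # up | down
    call: str  # oncogene_candidate | suppressor_candidate
    hr: float
    pvalue: float
    validation_consistent: bool


def call_key_genes(
    significant_fits: Sequence[CoxFit],
    directions: Mapping[str, str],
    rna_classes: Mapping[str, str],
    validation_de: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> list[KeyGeneCall]:
    """Concordance rule for key genes.

    up & HR > 1 -> oncogene candidate; down & HR < 1 -> suppressor
    candidate; anything discordant gets no call.  With a validation DE
    table (columns gene, direction, padj), ``validation_consistent``
    requires the same direction at padj < alpha; miRNAs skip validation.
    A significant gene whose DE direction is ``ns`` is excluded with a
    warning (inconsistent inputs).
    """
    validation: dict[str, tuple[str, float]] = {}
    if validation_de is not None:
        validation = {
            row["gene"]: (row["direction"], float(row["padj"]))
            for _, row in validation_de.iterrows()
        }
    calls = []
    for fit in significant_fits:
        direction = directions.get(fit.gene, "ns")
        if direction == "ns":
            log.warning("call_key_genes: %r prognostic but direction=ns; excluded", fit.gene)
            continue
        if direction == "up" and fit.hr > 1:
            call = "oncogene_candidate"
        elif direction == "down" and fit.hr < 1:
            call = "suppressor_candidate"
        else:
            continue
        rna_class = rna_classes.get(fit.gene, "mRNA")
        if validation_de is None or rna_class == "miRNA":
            consistent = True
        else:
            vdir, vpadj = validation.get(fit.gene, ("ns", 1.0))
            consistent = (vdir == direction) and (vpadj < alpha)
        calls.append(
            KeyGeneCall(fit.gene, rna_class, direction, call, fit.hr, fit.pvalue, consistent)
        )
    return calls


def key_gene_frame(calls: Sequence[KeyGeneCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(c) for c in calls],
        columns=["gene", "rna_class", "direction", "call", "hr", "pvalue",
                 "validation_consistent"],
    )
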