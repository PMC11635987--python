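"""Pipeline configuration.

All screening thresholds used across the pipeline live in a single
:class:`PipelineConfig` object: the per-cancer |log2FC| threshold and
adjusted-p cutoff for differential expression, the evidence thresholds for
miRNA-mRNA interaction pairs (number of supporting prediction databases and
CLIP experiments), the Cox and correlation significance levels, and the
over-representation-analysis cutoffs.  Per-cancer overrides of the fold-change
threshold are supported (e.g. a more permissive threshold for a cancer that
yields no axes under the common one).
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Mapping, Sequence
from pathlib import Path

import yaml

log = logging.getLogger(__name__)

DEFAULT_CANCERS: tuple[str, ...] = ("ESCA", "STAD", "LIHC", "COAD")

RNA_CLASSES: tuple[str, ...] = ("lncRNA", "miRNA", "mRNA")


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and panel definition for one pipeline run.

    Parameters
    ----------
    cancers
        Ordered, duplicate-free cancer identifiers of the compared panel.
    lfc_threshold
        Per-cancer |log2FC| threshold tau for calling a gene differentially
        expressed. A float applies to every cancer; a mapping overrides
        individual cancers (unlisted cancers keep the 1.0 default).
    padj_alpha
        BH-adjusted p cutoff for differential expression.
    min_support_db
        Minimum number of target-prediction databases (of seven) supporting
        a miRNA-mRNA pair.
    min_clip
        Minimum CLIP-experiment count supporting a miRNA-mRNA pair.
    cox_alpha
        Raw p cutoff of the univariate Cox prognostic screen.
    corr_alpha
        Raw p cutoff for the pairwise correlations of the axis filter.
    ora_min_overlap, ora_p_cutoff
        Over-representation analysis: minimum query/set overlap and raw
        hypergeometric p cutoff.
    seed
        Root seed for any randomized stage.
    """

    cancers: tuple[str, ...] = DEFAULT_CANCERS
    lfc_threshold: Mapping[str, float] | float = 1.0
    padj_alpha: float = 0.05
    min_support_db: int = 2
    min_clip: int = 1
    cox_alpha: float = 0.05
    corr_alpha: float = 0.05
    ora_min_overlap: int = 2
    ora_p_cutoff: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cancers:
            raise ValueError("cancers must be non-empty")
        if len(set(self.cancers)) != len(self.cancers):
            raise ValueError("cancers must be duplicate-free")
        object.__setattr__(self, "cancers", tuple(self.cancers))
        lfc = self.lfc_threshold
        if isinstance(lfc, Mapping):
            unknown = set(lfc) - set(self.cancers)
            if unknown:
                raise ValueError(f"lfc_threshold overrides unknown cancers: {sorted(unknown)}")
            table = {c: float(lfc.get(c, 1.0)) for c in self.cancers}
        else:
            table = {c: float(lfc) for c in self.cancers}
        for c, tau in table.items():
            if not tau > 0:
                raise ValueError(f"lfc_threshold for {c} must be strictly positive, got {tau}")
        object.__setattr__(self, "lfc_threshold", table)
        for name in ("padj_alpha", "cox_alpha", "corr_alpha", "ora_p_cutoff"):
            alpha = getattr(self, name)
            if not 0.0 < alpha < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {alpha}")
        for name in ("min_support_db", "min_clip", "ora_min_overlap"):
            value = getattr(self, name)
            if not (isinstance(value, int) and value > 0):
                raise ValueError(f"{name} must be a strictly positive integer, got {value!r}")

    def lfc_for(self, cancer: str) -> float:
        """|log2FC| threshold for one cancer of the panel."""
        try:
            return self.lfc_threshold[cancer]  # type: ignore[index]
        except KeyError:
            raise KeyError(f"unknown cancer {cancer!r}; panel is {list(self.cancers)}") from None


_CONFIG_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)}


def load_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file.

    Absent keys take their defaults; unknown keys are a hard error so typos
    do not silently fall back to defaults.  ``lfc_threshold`` may be a single
    number or a ``{cancer: tau}`` mapping of per-cancer overrides.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a key-value mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "cancers" in raw:
        raw["cancers"] = tuple(raw["cancers"])
    config = PipelineConfig(**raw)
    log.info("loaded config from %s: %s", path, config)
    return config
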