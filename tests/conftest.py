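import numpy as np
import pandas as pd
import pytest

from cernax import ExpressionMatrix


def make_matrix(
    counts: np.ndarray,
    n_tumor: int,
    rna_class: str = "mRNA",
    cancer: str = "ESCA",
    genes: list[str] | None = None,
) -> ExpressionMatrix:
    """ExpressionMatrix from a raw array; first n_tumor columns are tumor."""
    counts = np.asarray(counts, dtype=np.int64)
    n_genes, n_samples = counts.shape
    genes = genes or [f"G{i}" for i in range(1, n_genes + 1)]
    samples = [f"T{i}" for i in range(n_tumor)] + [
        f"N{i}" for i in range(n_samples - n_tumor)
    ]
    conditions = pd.Series(
        ["tumor"] * n_tumor + ["normal"] * (n_samples - n_tumor), index=samples
    )
    frame = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples)
    return ExpressionMatrix(frame, rna_class, cancer, conditions)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


def random_counts(rng, n_genes, n_samples, mean=100.0, phi=0.1):
    """NB counts with log-normal baselines, no planted structure."""
    base = rng.lognormal(np.log(mean), 1.0, size=n_genes)
    mu = np.tile(base[:, None], (1, n_samples))
    size = 1.0 / phi
    return rng.negative_binomial(size, size / (size + mu))
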