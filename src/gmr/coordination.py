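"""Expression coordination across biological replicas.

For the N adequately quantified genes of one condition, the Pearson
correlation ρ_ij of log2 gene-level expression is considered over all
N(N−1)/2 pairs.  A gene's coordination power is its mean squared
correlation with every other gene,

    CP_i = (1/(N−1)) Σ_{j≠i} ρ_ij²,

which rewards genes whose small expression oscillations are echoed — in
phase (synergistic) or in antiphase (antagonistic) — by many partners.
With few replicas per-pair correlations are individually weak evidence
(at λ = 4 the null expectation of ρ² is 1/(λ−1) = 1/3); the squared
correlations are therefore *aggregated* rather than tested pair by pair.

The all-pairs computation is blocked: the full N×N correlation matrix is
never materialized, only ``block_size`` × N slabs, yet the result equals
the dense computation exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gmr.datasets import ExpressionDataset
from gmr.errors import DataError, ValidationError

#: |rho| below this is reported as "independent" (no numeric threshold is
#: standard; this is the package's operational choice).
INDEPENDENCE_THRESHOLD = 0.05

DEFAULT_BLOCK_SIZE = 512


@dataclass
class CoordinationProfile:
    """Per-gene coordination power for one condition.

    ``cp`` is indexed by gene symbol; ``excluded`` lists genes dropped
    because their log2 expression has zero variance across replicas
    (correlation undefined).  ``strong_pairs`` optionally holds pairs
    with |ρ| at or above a caller-supplied threshold.
    """

    condition: str
    n_replicates: int
    cp: pd.Series
    excluded: tuple[str, ...] = ()
    strong_pairs: pd.DataFrame | None = None

    @property
    def grand_mean(self) -> float:
        """⟨CP⟩, the mean coordination power over all genes."""
        return float(self.cp.mean())

    @property
    def n_genes(self) -> int:
        return int(len(self.cp))


def _log2_zscores(dataset: ExpressionDataset) -> tuple[pd.Index, np.ndarray]:
    """Row-standardized log2 gene-level expression (unit-norm rows)."""
    if dataset.expression is None:
        raise DataError("run filter_probes / normalize_median first")
    gene_level = dataset.gene_expression()
    if (gene_level.to_numpy() <= 0).any():
        raise DataError("non-positive gene-level expression; cannot take log2")
    logs = np.log2(gene_level.to_numpy(float))
    logs -= logs.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(logs, axis=1)
    keep = norms > 0
    return gene_level.index[keep], logs[keep] / norms[keep, None]


def coordination_profile(
    dataset: ExpressionDataset,
    block_size: int = DEFAULT_BLOCK_SIZE,
    strong_threshold: float | None = None,
) -> CoordinationProfile:
    """Compute CP_i for every quantified gene.

    Genes whose expression is constant across replicas are excluded with
    N reduced accordingly.  ``strong_threshold`` (on |ρ|) optionally
    collects a sparse list of strongly correlated pairs while streaming
    the blocks.
    """
    if block_size < 1:
        raise ValidationError("block_size must be >= 1")
    genes, z = _log2_zscores(dataset)
    all_genes = dataset.gene_expression().index
    excluded = tuple(all_genes.difference(genes))
    n = len(genes)
    if n < 2:
        raise DataError("need at least two genes with replicate variance")

    cp = np.empty(n)
    pairs: list[tuple[str, str, float]] = []
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        slab = z[start:stop] @ z.T  # (block, N) correlations
        # subtract the self-correlation (exactly 1) from each row's sum
        cp[start:stop] = ((slab**2).sum(axis=1) - 1.0) / (n - 1)
        if strong_threshold is not None:
            rows, cols = np.nonzero(np.abs(slab) >= strong_threshold)
            for i, j in zip(rows, cols):
                gi, gj = genes[start + i], genes[j]
                if gi < gj:  # upper triangle only, no self pairs
                    pairs.append((gi, gj, float(slab[i, j])))

    strong = (
        pd.DataFrame(pairs, columns=["gene_a", "gene_b", "rho"])
        if strong_threshold is not None
        else None
    )
    return CoordinationProfile(
        condition=dataset.condition,
        n_replicates=dataset.n_replicates,
        cp=pd.Series(cp, index=genes, name="cp"),
        excluded=excluded,
        strong_pairs=strong,
    )


def critical_correlation(n_replicates: int, alpha: float = 0.05) -> float:
    """Two-sided critical |ρ| at level alpha for λ observations.

    From the t distribution with λ−2 degrees of freedom:
    ρ_crit = t / sqrt(t² + λ − 2) with t = t(1 − α/2; λ−2).
    """
    if n_replicates < 3:
        raise ValidationError("need at least 3 replicas for a correlation test")
    t = stats.t.ppf(1.0 - alpha / 2.0, n_replicates - 2)
    return float(t / np.sqrt(t**2 + n_replicates - 2))


def classify_pair(
    rho: float,
    n_replicates: int,
    alpha: float = 0.05,
    independence_threshold: float = INDEPENDENCE_THRESHOLD,
) -> str:
    """Label a pair correlation.

    ``synergistic`` (in-phase, ρ ≥ ρ_crit), ``antagonistic`` (antiphase,
    ρ ≤ −ρ_crit), ``independent`` (|ρ| below the independence threshold)
    or ``indeterminate`` otherwise.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValidationError(f"correlation must lie in [-1, 1], got {rho}")
    crit = critical_correlation(n_replicates, alpha)
    if rho >= crit:
        return "synergistic"
    if rho <= -crit:
        return "antagonistic"
    if abs(rho) < independence_threshold:
        return "independent"
    return "indeterminate"


def correlation_partners(
    dataset: ExpressionDataset,
    gene: str,
    top_k: int = 20,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Top-|ρ| partners of one gene, with classification labels.

    Ties in |ρ| are broken by gene symbol; ``top_k`` is clamped to the
    number of available partners.
    """
    genes, z = _log2_zscores(dataset)
    pos = genes.get_indexer([gene])
    if pos[0] < 0:
        raise DataError(f"gene {gene!r} not quantified (or zero variance)")
    rho = z[pos[0]] @ z.T
    table = pd.DataFrame({"partner": genes, "rho": rho})
    table = table[table["partner"] != gene]
    table["abs_rho"] = table["rho"].abs().round(12)
    table = table.sort_values(
        ["abs_rho", "partner"], ascending=[False, True]
    ).drop(columns="abs_rho")
    table = table.head(min(top_k, len(table))).reset_index(drop=True)
    table["label"] = [
        classify_pair(min(1.0, max(-1.0, r)), dataset.n_replicates, alpha)
        for r in table["rho"]
    ]
    return table
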