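"""Expression stability: REV and RES.

The Relative Expression Variation (REV) of gene *i* generalizes the
coefficient of variation to redundantly probed transcripts: the per-probe
CVs across the λ biological replicas are pooled in quadrature over the
gene's R_i probes and multiplied by a chi-square *mid-interval* correction
that accounts for estimating a CV from few observations,

    REV_i = c(r_i, ε) · sqrt( (1/R_i) Σ_k CV_ik² ),    r_i = λ·R_i − 1,

    c(r, ε) = ½ ( sqrt(r / χ²(r; 1−ε/2)) + sqrt(r / χ²(r; ε/2)) ),

where χ²(r; p) is the chi-square quantile at cumulative probability p.
c(r, ε) > 1 for all finite r and decreases toward 1 as the degrees of
freedom grow, so sparsely probed genes are penalized (their CV estimate
is more uncertain).

The Relative Expression Stability rescales REV against the condition's
median gene:

    RES_i = ln( ⟨REV⟩ / REV_i ),    ⟨REV⟩ = median REV over all genes,

so the median gene scores 0 and more stable genes score positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gmr.datasets import ExpressionDataset, GeneSet
from gmr.errors import DataError, ValidationError

#: ε values for which the mid-interval correction is meaningful; smaller
#: probabilities are swamped by technical noise in the expression levels.
EPSILON_GRID = (0.010, 0.025, 0.050, 0.100)

DEFAULT_EPSILON = 0.05

#: Genes with zero pooled CV get the smallest positive REV in the dataset
#: times this factor, keeping RES and GCH finite while preserving their
#: "most stable" rank; they are flagged in the summary table.
REV_FLOOR_FACTOR = 0.5


@dataclass
class DatasetSummary:
    """Per-gene stability summary of one condition.

    ``table`` is indexed by gene symbol with columns ``mean_expression``
    (μ, median units), ``n_probes`` (R), ``dof`` (r = λR − 1), ``rev``,
    ``res`` (NaN until :func:`res_per_gene`) and ``rev_floored``.
    """

    condition: str
    n_replicates: int
    epsilon: float
    table: pd.DataFrame

    @property
    def rev_median(self) -> float:
        """⟨REV⟩, the median REV over all quantified genes."""
        return float(self.table["rev"].median())


def chi2_midinterval_coefficient(r: int, epsilon: float = DEFAULT_EPSILON) -> float:
    """Mid-interval chi-square correction c(r, ε) for a pooled CV.

    Average of the two ends of the (1−ε) confidence interval for a
    standard deviation estimated with ``r`` degrees of freedom.  Strictly
    decreasing in r, with limit 1.
    """
    if not np.isclose(EPSILON_GRID, epsilon, atol=1e-12).any():
        raise ValidationError(
            f"epsilon must be one of {EPSILON_GRID}, got {epsilon}"
        )
    if r < 1 or int(r) != r:
        raise ValidationError(f"degrees of freedom must be a positive integer, got {r}")
    hi = stats.chi2.ppf(1.0 - epsilon / 2.0, r)
    lo = stats.chi2.ppf(epsilon / 2.0, r)
    return 0.5 * (np.sqrt(r / hi) + np.sqrt(r / lo))


def _probe_cv_table(dataset: ExpressionDataset) -> pd.DataFrame:
    """Per-probe replicate mean and CV (sample SD, λ−1 denominator)."""
    expr = dataset.expression
    values = expr.to_numpy(float)
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    return pd.DataFrame(
        {
            "gene_id": dataset.probes.loc[expr.index, "gene_id"],
            "mu": mu,
            "cv": np.divide(sd, mu, out=np.full_like(sd, np.nan), where=mu > 0),
        },
        index=expr.index,
    )


def rev_per_gene(
    dataset: ExpressionDataset, epsilon: float = DEFAULT_EPSILON
) -> DatasetSummary:
    """Compute per-gene REV for a filtered, normalized dataset.

    Genes with a non-positive probe mean are excluded with a warning (a
    CV cannot be formed); genes with zero pooled CV receive the floored
    REV and are flagged.
    """
    if dataset.expression is None:
        raise DataError("run filter_probes / normalize_median first")
    per_probe = _probe_cv_table(dataset)
    per_probe = per_probe[~dataset.probes.loc[per_probe.index, "is_control"]]

    bad_genes = set(per_probe.loc[per_probe["cv"].isna(), "gene_id"])
    if bad_genes:
        warnings.warn(
            f"excluding {len(bad_genes)} gene(s) with non-positive probe means"
        )
        per_probe = per_probe[~per_probe["gene_id"].isin(bad_genes)]
    if per_probe.empty:
        raise DataError("no genes left after excluding non-positive means")

    grouped = per_probe.groupby("gene_id")
    mu = grouped["mu"].mean()
    n_probes = grouped.size()
    pooled_cv = np.sqrt(grouped["cv"].apply(lambda c: float(np.mean(np.square(c)))))
    dof = dataset.n_replicates * n_probes - 1

    coeff = pd.Series(
        {r: chi2_midinterval_coefficient(int(r), epsilon) for r in dof.unique()}
    )
    rev = pooled_cv * dof.map(coeff)

    floored = rev == 0.0
    if floored.any():
        positive = rev[rev > 0]
        if positive.empty:
            raise DataError("all genes have zero variance; REV undefined")
        rev = rev.mask(floored, positive.min() * REV_FLOOR_FACTOR)

    table = pd.DataFrame(
        {
            "mean_expression": mu,
            "n_probes": n_probes.astype(int),
            "dof": dof.astype(int),
            "rev": rev,
            "res": np.nan,
            "rev_floored": floored,
        }
    ).sort_index()
    return DatasetSummary(
        condition=dataset.condition,
        n_replicates=dataset.n_replicates,
        epsilon=epsilon,
        table=table,
    )


def res_per_gene(summary: DatasetSummary) -> DatasetSummary:
    """Fill the RES column: RES_i = ln(⟨REV⟩ / REV_i)."""
    med = summary.rev_median
    if not np.isfinite(med) or med <= 0:
        raise DataError("median REV must be positive to compute RES")
    summary.table["res"] = np.log(med / summary.table["rev"])
    return summary


def pathway_mean_res(summary: DatasetSummary, gene_set: GeneSet) -> tuple[float, int]:
    """Mean RES over the quantified members of a gene set.

    Returns ``(mean_res, n_quantified)``; raises if no member was
    quantified in this condition.
    """
    if summary.table["res"].isna().all():
        raise DataError("run res_per_gene before pathway_mean_res")
    found = summary.table.index.intersection(gene_set.members)
    if found.empty:
        raise DataError(f"no member of {gene_set.set_id!r} is quantified")
    return float(summary.table.loc[found, "res"].mean()), int(len(found))
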