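"""Cancer-vs-normal regulation calls and Weighted Pathway Regulation.

The expression ratio is *signed*: x = μc/μn when cancer is higher and
x = −μn/μc when lower (x = +1 when equal), so |x| ≥ 1 always and the
sign carries the direction.  A gene counts as significantly regulated
when |x| exceeds its own cut-off

    CUT = 1 + sqrt( 2·(REV_cancer² + REV_normal²) ),

which folds both conditions' replicate noise into the threshold: tightly
controlled genes need only a small fold-change to be called, noisy genes
a large one.  The heteroscedastic (Welch) two-sided p-value is reported
alongside but does not enter the call.

Weighted Pathway Regulation scores a gene set by pondering *all*
quantified members, not just the called ones:

    WPR = ⟨ μ_i^(normal) · (|x_i| − 1) · (1 − p_i) ⟩ over members,

combining the expression level in the reference condition (median units),
the regulation magnitude (zero at no change in either direction) and the
confidence of the mean difference.  The magnitude term defaults to
|x| − 1, symmetric in direction; ``magnitude="literal"`` switches to
|x − 1|, which scores an unchanged down-direction gene (x = −1) as 2.
``weight="pathway_gch"`` replaces the per-gene μ^(normal) weight with the
pathway-average GCH.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from gmr.datasets import ExpressionDataset, GeneSet
from gmr.errors import DataError, ValidationError
from gmr.stability import DatasetSummary


def signed_fold_change(mu_a: float, mu_b: float) -> float:
    """Signed expression ratio of condition a (e.g. cancer) over b (normal)."""
    if mu_a <= 0 or mu_b <= 0:
        raise ValidationError("mean expressions must be strictly positive")
    if mu_a > mu_b:
        return mu_a / mu_b
    if mu_a < mu_b:
        return -mu_b / mu_a
    return 1.0


def cut_threshold(rev_a: float, rev_b: float) -> float:
    """Gene-specific absolute fold-change cut-off from the two REVs."""
    if rev_a < 0 or rev_b < 0:
        raise ValidationError("REV values must be non-negative")
    return 1.0 + np.sqrt(2.0 * (rev_a**2 + rev_b**2))


def welch_p(values_a, values_b) -> float:
    """Two-sided Welch (heteroscedastic) t-test p-value.

    Operates on per-replicate gene-level expressions; biological replicas
    are the unit of inference.  Degenerate zero-variance cases: p = 1
    for equal means, p = 0 for different means.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need at least two replicates per condition")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def regulation_calls(
    summary_a: DatasetSummary,
    summary_b: DatasetSummary,
    dataset_a: ExpressionDataset,
    dataset_b: ExpressionDataset,
) -> pd.DataFrame:
    """Per-gene regulation table of condition a (cancer) vs b (normal).

    Requires aligned datasets (identical gene universes).  Columns:
    ``gene``, ``x`` (signed ratio), ``cut``, ``p``, ``call`` in
    {up, down, not_significant}.  The call criterion is |x| > CUT alone.
    """
    genes_a = summary_a.table.index
    genes_b = summary_b.table.index
    if not genes_a.equals(genes_b):
        raise DataError(
            "gene universes differ; run align_conditions before regulation_calls"
        )
    va = dataset_a.gene_expression().loc[genes_a].to_numpy(float)
    vb = dataset_b.gene_expression().loc[genes_a].to_numpy(float)
    mu_a, mu_b = va.mean(axis=1), vb.mean(axis=1)
    if (mu_a <= 0).any() or (mu_b <= 0).any():
        raise ValidationError("mean expressions must be strictly positive")

    higher = mu_a > mu_b
    lower = mu_a < mu_b
    x = np.ones_like(mu_a)
    x[higher] = mu_a[higher] / mu_b[higher]
    x[lower] = -mu_b[lower] / mu_a[lower]

    rev_a = summary_a.table["rev"].to_numpy(float)
    rev_b = summary_b.table["rev"].to_numpy(float)
    cut = 1.0 + np.sqrt(2.0 * (rev_a**2 + rev_b**2))

    sd_a, sd_b = va.std(axis=1, ddof=1), vb.std(axis=1, ddof=1)
    degenerate = (sd_a == 0.0) & (sd_b == 0.0)
    # the Welch test is scale-invariant per gene; rescale to keep the
    # Welch-Satterthwaite df finite for extreme expression magnitudes
    scale = np.maximum(np.abs(va).max(axis=1), np.abs(vb).max(axis=1))
    scale = np.where(scale > 0, scale, 1.0)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.ttest_ind(va / scale, vb / scale, axis=1, equal_var=False).pvalue
    p = np.where(degenerate, np.where(mu_a == mu_b, 1.0, 0.0), p)

    call = np.where(
        np.abs(x) > cut,
        np.where(x >= 0, "up", "down"),
        "not_significant",
    )
    return pd.DataFrame(
        {"gene": genes_a, "x": x, "cut": cut, "p": p, "call": call}
    ).reset_index(drop=True)


def wpr(
    records: pd.DataFrame,
    mu_normal: pd.Series,
    gene_set: GeneSet,
    magnitude: str = "symmetric",
    weight: str = "normal_mean",
    pathway_gch: float | None = None,
) -> float:
    """Weighted Pathway Regulation of one gene set.

    Parameters
    ----------
    records : DataFrame from :func:`regulation_calls` (columns gene, x, p).
    mu_normal : per-gene mean expression in the reference condition
        (median units), indexed by gene symbol.
    gene_set : the pathway to score.
    magnitude : ``"symmetric"`` uses |x| − 1; ``"literal"`` uses |x − 1|.
    weight : ``"normal_mean"`` weights each member by μ^(normal);
        ``"pathway_gch"`` weights all members by ``pathway_gch`` (the
        pathway-average GCH, which the caller must supply).
    """
    if magnitude not in ("symmetric", "literal"):
        raise ValidationError(f"unknown magnitude mode {magnitude!r}")
    if weight not in ("normal_mean", "pathway_gch"):
        raise ValidationError(f"unknown weight mode {weight!r}")
    table = records.set_index("gene")
    members = table.index.intersection(gene_set.members)
    if members.empty:
        raise DataError(f"no member of {gene_set.set_id!r} is quantified")
    x = table.loc[members, "x"].to_numpy(float)
    p = table.loc[members, "p"].to_numpy(float)
    mag = np.abs(x) - 1.0 if magnitude == "symmetric" else np.abs(x - 1.0)
    if weight == "normal_mean":
        w = mu_normal.loc[members].to_numpy(float)
    else:
        if pathway_gch is None:
            raise ValidationError("weight='pathway_gch' needs the pathway_gch value")
        w = np.full(len(members), float(pathway_gch))
    return float(np.mean(w * mag * (1.0 - p)))
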