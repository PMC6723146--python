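"""Gene Commanding Height and the GMR hierarchy.

GCH combines stability and coordination into one positive score.  Two
forms are offered:

* ``approx4`` (default): GCH_i = (⟨REV⟩ / REV_i) · exp(4·CP_i) — the
  closed form whose scale matches published GMR hierarchies (top genes
  of order 40–170); the coordination factor is bounded in [1, e⁴].
* ``exact_ratio``: GCH_i = exp(RES_i + CP_i / ⟨CP⟩) — the definitional
  form in which each gene's coordination power is taken relative to the
  condition's grand-mean CP.

The two coincide only when ⟨CP⟩ = 1/4; at λ = 4 the null expectation of
ρ² is 1/3, so they generally differ in scale (both are monotone in RES
and CP, hence agree on ordering when ⟨CP⟩ is fixed).

The condition's GMR is the rank-1 gene.  It is *actionable* when its GCH
stands well above the runner-up (gap ratio ≥ 1.5 by default — published
hierarchies call a ~1.7× gap clearly actionable and a ~1.0× gap not).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gmr.coordination import CoordinationProfile
from gmr.errors import DataError, ValidationError
from gmr.stability import DatasetSummary

GCH_FORMS = ("approx4", "exact_ratio")

DEFAULT_GAP_THRESHOLD = 1.5
DEFAULT_TOP_K = 3


@dataclass(frozen=True)
class GMRCall:
    """The Gene Master Regulator call for one condition."""

    condition: str
    gmr_gene: str
    top_gch: float
    second_gene: str
    second_gch: float
    gap_ratio: float
    actionable: bool

    def as_dict(self) -> dict:
        return {
            "condition": self.condition,
            "gmr_gene": self.gmr_gene,
            "top_gch": self.top_gch,
            "second_gene": self.second_gene,
            "second_gch": self.second_gch,
            "gap_ratio": self.gap_ratio,
            "actionable": self.actionable,
        }


def gch_scores(
    summary: DatasetSummary,
    profile: CoordinationProfile,
    form: str = "approx4",
) -> pd.DataFrame:
    """Per-gene GCH from a stability summary and a coordination profile.

    Both inputs must cover the same gene universe (genes dropped by one
    stage but not the other are an error: reconcile upstream).  Returns
    a ranked table with columns ``gene``, ``gch``, ``rank`` and the form
    recorded in ``DataFrame.attrs["form"]``.
    """
    if form not in GCH_FORMS:
        raise ValidationError(f"form must be one of {GCH_FORMS}, got {form!r}")
    genes = summary.table.index
    if not genes.equals(profile.cp.index.sort_values()):
        raise DataError("stability and coordination cover different gene universes")
    rev = summary.table["rev"]
    if (rev <= 0).any():
        raise DataError("non-positive REV; apply the REV floor first")
    cp = profile.cp.reindex(genes)

    if form == "approx4":
        gch = (summary.rev_median / rev) * np.exp(4.0 * cp)
    else:
        res = summary.table["res"]
        if res.isna().any():
            raise DataError("run res_per_gene before the exact_ratio form")
        gch = np.exp(res + cp / profile.grand_mean)

    table = pd.DataFrame({"gene": genes, "gch": gch.to_numpy(float)})
    table.attrs["form"] = form
    table.attrs["condition"] = summary.condition
    return rank_genes(table)


def rank_genes(records: pd.DataFrame) -> pd.DataFrame:
    """Sort by descending GCH (ties by gene symbol) and assign ranks 1..N."""
    if records.empty:
        raise DataError("cannot rank an empty GCH table")
    attrs = dict(records.attrs)
    out = records.sort_values(
        ["gch", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out.attrs.update(attrs)
    return out


def gmr_call(
    ranked: pd.DataFrame,
    gap_threshold: float = DEFAULT_GAP_THRESHOLD,
    condition: str | None = None,
) -> GMRCall:
    """Call the GMR from a ranked GCH table.

    ``actionable`` is True when top GCH / second GCH >= gap_threshold.
    """
    if len(ranked) < 2:
        raise DataError("need at least two genes to call a GMR")
    ordered = ranked.sort_values("rank")
    top, second = ordered.iloc[0], ordered.iloc[1]
    gap = float(top["gch"] / second["gch"])
    return GMRCall(
        condition=condition or ranked.attrs.get("condition", ""),
        gmr_gene=str(top["gene"]),
        top_gch=float(top["gch"]),
        second_gene=str(second["gene"]),
        second_gch=float(second["gch"]),
        gap_ratio=gap,
        actionable=gap >= gap_threshold,
    )


def cross_condition_table(
    tables: dict[str, pd.DataFrame], top_k: int = DEFAULT_TOP_K
) -> pd.DataFrame:
    """Matrix of the per-condition top genes' GCH across all conditions.

    For each condition's top-k genes, report the gene's GCH in every
    condition; NaN where the gene is not quantified there (rendered
    ``N/A`` on output).  Rows keep condition-of-origin order, then rank.
    """
    if len(tables) < 2:
        raise DataError("need at least two conditions")
    lookup = {
        cond: table.set_index("gene")["gch"] for cond, table in tables.items()
    }
    union = set()
    for series in lookup.values():
        union |= set(series.index)
    if not any(
        set(a.index) & set(b.index)
        for a in lookup.values()
        for b in lookup.values()
        if a is not b
    ):
        raise DataError("conditions share no genes")

    rows: list[dict] = []
    seen: set[str] = set()
    for cond, table in tables.items():
        top = table.sort_values("rank").head(top_k)
        for _, rec in top.iterrows():
            gene = str(rec["gene"])
            if gene in seen:
                continue
            seen.add(gene)
            row = {"gene": gene, "top_in": cond, "rank_in_top": int(rec["rank"])}
            for other, series in lookup.items():
                row[f"gch_{other}"] = float(series.get(gene, np.nan))
            rows.append(row)
    return pd.DataFrame(rows)


def concordance_report(
    gch_a: pd.Series,
    gch_b: pd.Series,
    wpr_a: pd.Series,
    wpr_b: pd.Series,
) -> tuple[pd.DataFrame, float]:
    """Check that GCH differences predict perturbation-consequence differences.

    For every perturbed gene g, concordance means sign(GCH_g^A − GCH_g^B)
    equals sign(WPR_g^A − WPR_g^B): manipulating a gene's expression has
    the larger transcriptome-wide consequence in the condition where the
    gene sits higher in the GCH hierarchy.  Returns the per-gene flag
    table and the concordant fraction.
    """
    gch_a, gch_b = pd.Series(gch_a), pd.Series(gch_b)
    wpr_a, wpr_b = pd.Series(wpr_a), pd.Series(wpr_b)
    idx = gch_a.index
    for other in (gch_b, wpr_a, wpr_b):
        if len(other) != len(idx) or not idx.sort_values().equals(
            other.index.sort_values()
        ):
            raise DataError("the four inputs must cover the same perturbed genes")
    table = pd.DataFrame(
        {
            "gch_a": gch_a,
            "gch_b": gch_b.reindex(idx),
            "wpr_a": wpr_a.reindex(idx),
            "wpr_b": wpr_b.reindex(idx),
        }
    )
    table["concordant"] = np.sign(table["gch_a"] - table["gch_b"]) == np.sign(
        table["wpr_a"] - table["wpr_b"]
    )
    return table, float(table["concordant"].mean())
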