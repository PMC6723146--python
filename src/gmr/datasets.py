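"""Core data model and file formats.

A condition is one :class:`ExpressionDataset`: probe-level foreground /
background fluorescence intensities for ``n_replicates`` (λ ≥ 4) biological
replicas, plus per-spot pixel-quality flags, and — after QC and median
normalization — a probe × replicate matrix of net expression in *median
units* (the median quantified gene per replicate equals 1).

Probe redundancy is first-class: several probes may interrogate the same
gene symbol (on Agilent 4×44k style arrays between 1 and ~28 spots per
transcript), and all per-gene statistics pool the redundant probes.

Gene symbols are taken verbatim and case-sensitively; no alias resolution
is attempted.  Cross-condition analyses only assume shared gene symbols,
never shared probe order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from gmr.errors import DataError, FormatError, ValidationError

MIN_REPLICATES = 4

_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}


@dataclass
class ExpressionDataset:
    """Probe-level expression data for one condition.

    Parameters
    ----------
    condition : str
        Label of the condition (e.g. ``"cancer"``).
    n_replicates : int
        Number of biological replicas λ; at least 4.
    probes : pandas.DataFrame
        Indexed by ``probe_id`` (unique); columns ``gene_id``,
        ``is_control`` and, for each replicate k, ``fg_k``, ``bg_k``
        (non-negative fluorescence) and ``ok_k`` (pixel-quality flag).
    expression : pandas.DataFrame, optional
        Probe × replicate net intensities (columns ``rep_1..rep_λ``),
        populated by QC/normalization; aligned with ``probes.index``.
    normalized : bool
        True once every replicate has been scaled to unit gene-level
        median.
    """

    condition: str
    n_replicates: int
    probes: pd.DataFrame
    expression: pd.DataFrame | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.n_replicates < MIN_REPLICATES:
            raise ValidationError(
                f"need at least {MIN_REPLICATES} biological replicas, "
                f"got {self.n_replicates}"
            )
        if self.probes.index.has_duplicates:
            dup = self.probes.index[self.probes.index.duplicated()][0]
            raise FormatError(f"duplicate probe_id {dup!r}")
        if self.expression is not None and not self.expression.index.equals(
            self.probes.index
        ):
            raise ValidationError("expression matrix not aligned with probes")

    # -- derived views -------------------------------------------------

    @property
    def replicate_columns(self) -> list[str]:
        return [f"rep_{k}" for k in range(1, self.n_replicates + 1)]

    @property
    def genes(self) -> list[str]:
        """Sorted list of non-control gene symbols."""
        return sorted(self.probes.loc[~self.probes["is_control"], "gene_id"].unique())

    @property
    def gene_index(self) -> dict[str, list[str]]:
        """Mapping gene symbol -> list of its probe ids (size R_i >= 1)."""
        sub = self.probes.loc[~self.probes["is_control"], "gene_id"]
        return {g: list(ix) for g, ix in sub.groupby(sub).groups.items()}

    @property
    def n_genes(self) -> int:
        return self.probes.loc[~self.probes["is_control"], "gene_id"].nunique()

    def gene_expression(self) -> pd.DataFrame:
        """Gene-level expression: mean over each gene's probes, per replicate.

        Requires a populated ``expression`` matrix (run QC first).
        Returns a gene × replicate DataFrame sorted by gene symbol.
        """
        if self.expression is None:
            raise DataError("expression matrix not populated; run filter_probes first")
        gene_ids = self.probes.loc[self.expression.index, "gene_id"]
        return self.expression.groupby(gene_ids).mean().sort_index()

    def restrict_genes(self, genes) -> "ExpressionDataset":
        """Subset to probes of the given gene symbols (order preserved)."""
        keep = self.probes["gene_id"].isin(set(genes))
        probes = self.probes.loc[keep]
        expr = self.expression.loc[keep[keep].index] if self.expression is not None else None
        return replace(self, probes=probes, expression=expr)


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols (e.g. one KEGG pathway)."""

    set_id: str
    name: str
    members: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"gene set {self.set_id!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise FormatError(f"gene set {self.set_id!r} has duplicate members")


# ---------------------------------------------------------------------------
# probe table TSV


def _parse_bool(column: pd.Series, name: str) -> pd.Series:
    as_str = column.astype(str).str.strip().str.lower()
    bad = ~as_str.isin(_TRUE | _FALSE)
    if bad.any():
        row = column.index[bad][0]
        raise FormatError(f"non-boolean value in column {name!r} at row {row!r}")
    return as_str.isin(_TRUE)


def read_probe_table(path, n_replicates: int) -> ExpressionDataset:
    """Read a probe-level TSV into an :class:`ExpressionDataset`.

    The file must carry a header with columns ``probe_id``, ``gene_id``,
    ``is_control`` and, for each replicate ``k = 1..n_replicates``,
    ``fg_k``, ``bg_k`` and ``ok_k``.  No filtering happens here.
    """
    if n_replicates < MIN_REPLICATES:
        raise ValidationError(
            f"need at least {MIN_REPLICATES} biological replicas, got {n_replicates}"
        )
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    needed = ["probe_id", "gene_id", "is_control"]
    for k in range(1, n_replicates + 1):
        needed += [f"fg_{k}", f"bg_{k}", f"ok_{k}"]
    for col in needed:
        if col not in table.columns:
            raise FormatError(f"{path.name}: missing column {col!r}")
    table = table.set_index("probe_id")
    if table.index.has_duplicates:
        dup = table.index[table.index.duplicated()][0]
        raise FormatError(f"{path.name}: duplicate probe_id {dup!r}")
    out = pd.DataFrame(index=table.index)
    out["gene_id"] = table["gene_id"].astype(str)
    out["is_control"] = _parse_bool(table["is_control"], "is_control")
    for k in range(1, n_replicates + 1):
        for kind in ("fg", "bg"):
            col = f"{kind}_{k}"
            vals = pd.to_numeric(table[col], errors="coerce")
            if vals.isna().any():
                row = vals.index[vals.isna()][0]
                raise FormatError(
                    f"{path.name}: non-numeric intensity in column {col!r} "
                    f"at probe {row!r}"
                )
            if (vals < 0).any():
                row = vals.index[vals < 0][0]
                raise FormatError(
                    f"{path.name}: negative intensity in column {col!r} at probe {row!r}"
                )
            out[col] = vals.astype(float)
        out[f"ok_{k}"] = _parse_bool(table[f"ok_{k}"], f"ok_{k}")
    return ExpressionDataset(condition=path.stem, n_replicates=n_replicates, probes=out)


def write_probe_table(dataset: ExpressionDataset, path) -> None:
    """Write the raw probe table back to TSV (inverse of read_probe_table)."""
    table = dataset.probes.copy()
    for col in table.columns:
        if table[col].dtype == bool:
            table[col] = table[col].astype(int)
    table.to_csv(path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gene_sets_gmt(path) -> list[GeneSet]:
    """Read gene sets from a standard GMT file.

    One set per line: ``set_id <TAB> description <TAB> member [<TAB> member...]``.
    Duplicate members within a line are dropped with a warning.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    n_dupes = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path.name}:{lineno}: GMT line needs id, description and "
                    f"at least one member ({len(fields)} fields found)"
                )
            set_id, name, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            n_dupes += len(members) - len(unique)
            if not unique:
                raise FormatError(f"{path.name}:{lineno}: gene set with no members")
            sets.append(GeneSet(set_id=set_id, name=name, members=tuple(unique)))
    if n_dupes:
        warnings.warn(f"{path.name}: dropped {n_dupes} duplicate gene-set members")
    return sets


# ---------------------------------------------------------------------------
# result tables


def write_report_csv(records: pd.DataFrame, path) -> None:
    """Write a result table to CSV with floats at 6 significant digits."""
    if records is None or len(records) == 0:
        raise DataError("refusing to write an empty report")
    records.to_csv(path, index=False, float_format="%.6g")


def read_report_csv(path) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_report_csv`."""
    return pd.read_csv(path)
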