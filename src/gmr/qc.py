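"""Probe-level quality control and median normalization.

Spot exclusion follows two-color microarray practice: control spots,
spots with corrupted/saturated pixels in any replica, and spots whose
foreground fluorescence is less than twice the background in any of the
λ replicas are removed from that condition.  Survivors get a net signal
fg − bg, strictly positive by the low-signal rule (a spot with
fg exactly = 2·bg is retained — removal requires *less than* twice).

Normalization is per-replicate median scaling on the linear scale: every
net intensity is divided by that replicate's median *gene-level*
expression, so that afterwards the median quantified gene equals 1 in
every replicate ("median units").  This is the simplest transform
consistent with reporting average expression normalized to the median of
all quantified transcripts; lab-specific normalization pipelines may
differ.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from gmr.datasets import ExpressionDataset
from gmr.errors import DataError


@dataclass(frozen=True)
class QCReport:
    """Accounting of the spot-exclusion step."""

    n_input: int
    removed_control: int
    removed_pixel_flag: int
    removed_low_signal: int
    probes_retained: int
    genes_retained: int

    def __post_init__(self) -> None:
        removed = self.removed_control + self.removed_pixel_flag + self.removed_low_signal
        if removed + self.probes_retained != self.n_input:
            raise ValueError("QC accounting does not add up")

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed_control": self.removed_control,
            "removed_pixel_flag": self.removed_pixel_flag,
            "removed_low_signal": self.removed_low_signal,
            "probes_retained": self.probes_retained,
            "genes_retained": self.genes_retained,
        }


def filter_probes(dataset: ExpressionDataset) -> tuple[ExpressionDataset, QCReport]:
    """Apply the spot-exclusion rules and compute net expression.

    Removal reasons, in precedence order (each probe is counted once):

    1. ``control`` — the probe is a control spot;
    2. ``pixel_flag`` — a corrupted/saturated pixel in any replicate;
    3. ``low_signal`` — foreground < 2×background (or no positive net
       signal) in any replicate.

    Returns the filtered dataset with ``expression`` = fg − bg and a
    :class:`QCReport`.  Idempotent: running it again removes nothing.
    """
    probes = dataset.probes
    reps = range(1, dataset.n_replicates + 1)
    fg = probes[[f"fg_{k}" for k in reps]].to_numpy(float)
    bg = probes[[f"bg_{k}" for k in reps]].to_numpy(float)
    ok = probes[[f"ok_{k}" for k in reps]].to_numpy(bool)

    is_control = probes["is_control"].to_numpy(bool)
    bad_pixel = ~ok.all(axis=1)
    # strict inequality: fg exactly 2*bg is retained; the net-signal clause
    # only matters when bg == 0
    low_signal = ((fg < 2.0 * bg) | (fg - bg <= 0.0)).any(axis=1)

    reason_control = is_control
    reason_pixel = bad_pixel & ~is_control
    reason_low = low_signal & ~bad_pixel & ~is_control
    keep = ~(reason_control | reason_pixel | reason_low)

    if not keep.any():
        raise DataError("no probes survive QC")

    kept = probes.loc[keep].copy()
    net = pd.DataFrame(
        (fg - bg)[keep],
        index=kept.index,
        columns=[f"rep_{k}" for k in reps],
    )
    filtered = replace(dataset, probes=kept, expression=net, normalized=False)
    report = QCReport(
        n_input=len(probes),
        removed_control=int(reason_control.sum()),
        removed_pixel_flag=int(reason_pixel.sum()),
        removed_low_signal=int(reason_low.sum()),
        probes_retained=int(keep.sum()),
        genes_retained=filtered.n_genes,
    )
    return filtered, report


def normalize_median(dataset: ExpressionDataset) -> ExpressionDataset:
    """Scale each replicate so its median gene-level expression is 1.

    Scale-invariant (multiplying a replicate's raw intensities by any
    c > 0 yields the same result) and idempotent.
    """
    if dataset.expression is None:
        raise DataError("run filter_probes before normalization")
    gene_level = dataset.gene_expression()
    medians = gene_level.median(axis=0)
    if (medians <= 0).any() or medians.isna().any():
        raise DataError("non-positive median gene-level expression in a replicate")
    expr = dataset.expression / medians
    return replace(dataset, expression=expr, normalized=True)


def align_conditions(
    a: ExpressionDataset, b: ExpressionDataset
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Restrict two filtered datasets to their common gene symbols.

    Filtering is per-condition, so cross-condition comparisons need a
    common gene universe; probe order is never assumed shared, only gene
    symbols.
    """
    common = set(a.genes) & set(b.genes)
    if not common:
        raise DataError(
            f"conditions {a.condition!r} and {b.condition!r} share no genes"
        )
    return a.restrict_genes(common), b.restrict_genes(common)
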