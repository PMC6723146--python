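"""End-to-end runs: QC → stability → coordination → GCH → reports.

Every run writes a manifest (inputs with SHA-256 hashes, full parameter
set, package version) so that two runs with equal manifests produce
byte-identical CSV bodies.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

import gmr
from gmr.coordination import DEFAULT_BLOCK_SIZE, coordination_profile
from gmr.datasets import (
    ExpressionDataset,
    read_gene_sets_gmt,
    read_probe_table,
    write_report_csv,
)
from gmr.errors import ValidationError
from gmr.qc import align_conditions, filter_probes, normalize_median
from gmr.ranking import (
    DEFAULT_GAP_THRESHOLD,
    DEFAULT_TOP_K,
    cross_condition_table,
    gch_scores,
    gmr_call,
)
from gmr.regulation import regulation_calls, wpr
from gmr.stability import DEFAULT_EPSILON, res_per_gene, rev_per_gene

log = logging.getLogger("gmr")


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Global parameters of a pipeline run."""

    epsilon: float = DEFAULT_EPSILON
    n_replicates: int = 4
    gch_form: str = "approx4"
    gap_threshold: float = DEFAULT_GAP_THRESHOLD
    top_k: int = DEFAULT_TOP_K
    wpr_magnitude: str = "symmetric"
    wpr_weight: str = "normal_mean"
    block_size: int = DEFAULT_BLOCK_SIZE
    seed: int | None = None

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _write_manifest(outdir: Path, config: RunConfig, inputs: list[Path]) -> None:
    manifest = {
        "package_version": gmr.__version__,
        "config": config.as_dict(),
        "inputs": [{"path": str(p), "sha256": _sha256(p)} for p in inputs],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _prepare(path: Path, config: RunConfig):
    dataset = read_probe_table(path, config.n_replicates)
    filtered, report = filter_probes(dataset)
    log.info(
        "%s: %d/%d probes retained (%d genes)",
        dataset.condition, report.probes_retained, report.n_input,
        report.genes_retained,
    )
    return normalize_median(filtered), report


def _rank_one(dataset: ExpressionDataset, config: RunConfig):
    summary = res_per_gene(rev_per_gene(dataset, config.epsilon))
    profile = coordination_profile(dataset, block_size=config.block_size)
    if profile.excluded:
        summary.table = summary.table.drop(index=list(profile.excluded), errors="ignore")
    ranked = gch_scores(summary, profile, form=config.gch_form)
    return summary, profile, ranked


def run_rank(config: RunConfig, input_path, outdir) -> dict:
    """Full single-condition run; writes qc.json, summary.csv, gch.csv,
    gmr_call.json and manifest.json into ``outdir``."""
    input_path, outdir = Path(input_path), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset, report = _prepare(input_path, config)
    summary, profile, ranked = _rank_one(dataset, config)
    call = gmr_call(ranked, config.gap_threshold, condition=dataset.condition)

    (outdir / "qc.json").write_text(json.dumps(report.as_dict(), indent=2))
    write_report_csv(
        summary.table.reset_index(names="gene"), outdir / "summary.csv"
    )
    write_report_csv(ranked[["gene", "gch", "rank"]], outdir / "gch.csv")
    (outdir / "gmr_call.json").write_text(json.dumps(call.as_dict(), indent=2))
    _write_manifest(outdir, config, [input_path])
    log.info("%s: GMR = %s (GCH %.2f, gap %.2f)", dataset.condition,
             call.gmr_gene, call.top_gch, call.gap_ratio)
    return {"qc": report, "summary": summary, "ranked": ranked, "call": call}


def run_compare(config: RunConfig, input_paths, outdir, gmt_path=None) -> dict:
    """Multi-condition run: cross-condition GCH table plus, for every
    other condition against the first (reference / "normal"), regulation
    calls and per-pathway WPR."""
    paths = [Path(p) for p in input_paths]
    if len(paths) < 2:
        raise ValidationError("need at least two input tables to compare")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    datasets = []
    seen_labels: set[str] = set()
    for path in paths:
        dataset, _ = _prepare(path, config)
        # disambiguate conditions loaded from identically named files
        label, k = dataset.condition, 2
        while label in seen_labels:
            label = f"{dataset.condition}_{k}"
            k += 1
        seen_labels.add(label)
        dataset.condition = label
        datasets.append(dataset)

    ranked_tables = {}
    for dataset in datasets:
        _, _, ranked = _rank_one(dataset, config)
        ranked_tables[dataset.condition] = ranked
    matrix = cross_condition_table(ranked_tables, top_k=config.top_k)
    matrix_out = matrix.copy()
    for col in matrix_out.columns:
        if col.startswith("gch_"):
            matrix_out[col] = matrix_out[col].map(
                lambda v: "N/A" if pd.isna(v) else f"{v:.6g}"
            )
    write_report_csv(matrix_out, outdir / "cross_condition.csv")

    gene_sets = read_gene_sets_gmt(gmt_path) if gmt_path else []
    reference = datasets[0]
    pathway_rows = []
    for other in datasets[1:]:
        ref_al, oth_al = align_conditions(reference, other)
        sum_ref = rev_per_gene(ref_al, config.epsilon)
        sum_oth = rev_per_gene(oth_al, config.epsilon)
        common = sum_ref.table.index.intersection(sum_oth.table.index)
        sum_ref.table, sum_oth.table = sum_ref.table.loc[common], sum_oth.table.loc[common]
        records = regulation_calls(sum_oth, sum_ref, oth_al, ref_al)
        write_report_csv(records, outdir / f"regulation_{other.condition}.csv")
        for gene_set in gene_sets:
            try:
                value = wpr(
                    records, sum_ref.table["mean_expression"], gene_set,
                    magnitude=config.wpr_magnitude,
                )
            except Exception:
                continue
            pathway_rows.append((other.condition, gene_set.set_id, gene_set.name, value))
    if pathway_rows:
        write_report_csv(
            pd.DataFrame(
                pathway_rows, columns=["condition", "set_id", "set_name", "wpr"]
            ),
            outdir / "wpr.csv",
        )
    _write_manifest(outdir, config, paths)
    return {"cross_condition": matrix, "n_pathways": len(pathway_rows)}
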