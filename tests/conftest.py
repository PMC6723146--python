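"""Shared fixtures: tiny hand-built datasets, probe-table files, gene sets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gmr.datasets import ExpressionDataset, GeneSet


def make_expression_dataset(
    gene_probe_values: dict[str, list[list[float]]],
    condition: str = "test",
    normalized: bool = True,
) -> ExpressionDataset:
    """Build a post-QC dataset directly from probe-level values.

    ``gene_probe_values`` maps gene symbol -> list of probes, each a list
    of λ replicate intensities.  Bypasses the fg/bg representation so
    tests can state expression values exactly.
    """
    lam = len(next(iter(gene_probe_values.values()))[0])
    probe_ids, gene_ids, rows = [], [], []
    for gene, probes in gene_probe_values.items():
        for k, values in enumerate(probes):
            probe_ids.append(f"{gene}_p{k + 1}")
            gene_ids.append(gene)
            rows.append(values)
    probes = pd.DataFrame(
        {"gene_id": gene_ids, "is_control": False},
        index=pd.Index(probe_ids, name="probe_id"),
    )
    expression = pd.DataFrame(
        np.asarray(rows, float),
        index=probes.index,
        columns=[f"rep_{k}" for k in range(1, lam + 1)],
    )
    return ExpressionDataset(
        condition=condition,
        n_replicates=lam,
        probes=probes,
        expression=expression,
        normalized=normalized,
    )


def write_probe_tsv(path, rows: list[dict], n_replicates: int = 4) -> None:
    """Write a raw probe table TSV from dicts with keys probe_id, gene_id,
    is_control, fg (list), bg (list), ok (list)."""
    header = ["probe_id", "gene_id", "is_control"]
    for k in range(1, n_replicates + 1):
        header += [f"fg_{k}", f"bg_{k}", f"ok_{k}"]
    lines = ["\t".join(header)]
    for row in rows:
        fields = [row["probe_id"], row["gene_id"], str(int(row.get("is_control", False)))]
        for k in range(n_replicates):
            fields += [
                str(row["fg"][k]),
                str(row["bg"][k]),
                str(int(row.get("ok", [True] * n_replicates)[k])),
            ]
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")


def simple_probe_rows(n_replicates: int = 4) -> list[dict]:
    """Six probes over five genes: one gene probed twice, all clean."""
    rows = []
    specs = [
        ("p1", "GENE_A", [400, 410, 390, 405]),
        ("p2", "GENE_A", [350, 360, 340, 355]),
        ("p3", "GENE_B", [800, 820, 790, 810]),
        ("p4", "GENE_C", [120, 125, 118, 122]),
        ("p5", "GENE_D", [990, 1000, 985, 995]),
        ("p6", "GENE_E", [260, 255, 265, 258]),
    ]
    for probe_id, gene, fg in specs:
        rows.append(
            {"probe_id": probe_id, "gene_id": gene,
             "fg": fg[:n_replicates], "bg": [50] * n_replicates}
        )
    return rows


@pytest.fixture
def probe_table_path(tmp_path):
    path = tmp_path / "probes.tsv"
    write_probe_tsv(path, simple_probe_rows())
    return path


#: The seven-pathway KEGG panel used throughout: apoptosis, basal
#: transcription factors, cell cycle, chemokine signaling, oxidative
#: phosphorylation, renal cell carcinoma, RNA polymerase.
KEGG_PANEL = [
    ("hsa04210", "APO", ["TP53", "BAX", "CASP3", "BCL2"]),
    ("hsa03022", "BTF", ["TAF1", "GTF2B", "TBP"]),
    ("hsa04110", "CCY", ["CDK1", "CCNB1", "CDC20"]),
    ("hsa04062", "CSP", ["CCL2", "CXCR4", "STAT3"]),
    ("hsa00190", "OXP", ["NDUFA1", "COX5A", "ATP5F1A"]),
    ("hsa05211", "RCC", ["VHL", "HIF1A", "MET"]),
    ("hsa03020", "RPO", ["POLR2A", "POLR2B"]),
]


@pytest.fixture
def kegg_gmt_path(tmp_path):
    path = tmp_path / "panel.gmt"
    lines = [
        "\t".join([set_id, name, *members]) for set_id, name, members in KEGG_PANEL
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def small_gene_set():
    return GeneSet("hsa04210", "APO", ("GENE_A", "GENE_B"))
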