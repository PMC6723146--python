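"""Synthetic probe-level datasets with a planted Gene Master Regulator.

The generator emulates the structure of two-color 4×44k-style expression
data: redundant probes per gene (R ∈ 1..28), heterogeneous per-gene
replicate noise, and a latent per-replicate factor that correlates the
loaded genes.  Gene *i* in replicate *j* has log2 expression

    b_i + β_i · F_j          (shared across the gene's probes)

with F_j standard normal per replicate; probe *k* adds a fixed affinity
offset N(0, probe_offset_sd) and an independent per-spot measurement
noise N(0, σ_i) per replicate.  Placing the per-gene noise at the spot
level (hybridization noise, independent across redundant probes) matches
the degrees-of-freedom accounting r = λR − 1 used by the pooled-CV
estimator; truly shared biological variation beyond the latent factor is
not modeled.

Loadings are standardized (factor-analysis convention): a gene's loading
ℓ is its correlation with the factor at the gene level, achieved with a
factor coefficient β_i = σ_i·ℓ/sqrt(1−ℓ²).  The planted GMR combines a
large baseline (×20), a tiny residual SD (0.02 log2) and a high loading
(0.8), so it is simultaneously the most stable and among the most
coordinated genes — the configuration a real master regulator is
hypothesized to occupy.

Linear intensities are scaled to fluorescence units with an additive
background, so the probe tables exercise the full QC path.  Randomness
uses one root seed with documented per-gene stream splitting: adding
genes to a config never reshuffles the draws of existing genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from gmr.datasets import ExpressionDataset, GeneSet
from gmr.errors import DataError, ValidationError
from gmr.qc import filter_probes, normalize_median
from gmr.regulation import regulation_calls, wpr
from gmr.stability import rev_per_gene

# sub-stream tags for the seed sequence [seed, tag, ...]
_PARAMS, _NOISE, _FACTOR, _EFFECTS, _QC = 0, 1, 2, 3, 4

MAX_PROBES = 28


@dataclass(frozen=True)
class PlantedGene:
    """Overrides for one planted gene.

    ``None`` fields keep the background draw, so the same mechanism also
    plants "decoy" genes that share the GMR's expression level but not
    its stability or coordination.
    """

    index: int = 0
    mean_multiplier: float = 20.0
    residual_sd: float | None = 0.02
    loading: float | None = 0.8
    n_probes: int | None = 8


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults are the package's study conditions."""

    n_genes: int = 500
    n_replicates: int = 4
    seed: int = 0
    condition: str = "synthetic"
    #: truncated geometric success probability for probe counts R in 1..28
    probe_geometric_p: float = 0.45
    #: log2 SD of the lognormal baseline-abundance law (median-unit scale)
    baseline_log2_sd: float = 1.5
    #: fraction of genes loaded on the shared replicate factor
    loaded_fraction: float = 0.3
    #: standardized loading range for loaded genes (correlation with factor)
    loading_range: tuple[float, float] = (0.3, 0.7)
    #: per-gene spot-level log2 noise SD range
    residual_sd_range: tuple[float, float] = (0.2, 0.6)
    #: SD of fixed per-probe affinity offsets (log2)
    probe_offset_sd: float = 0.25
    #: linear-to-fluorescence scale and additive background range
    intensity_scale: float = 500.0
    background_range: tuple[float, float] = (20.0, 60.0)
    #: fraction of extra control spots and per-spot bad-pixel rate
    control_fraction: float = 0.01
    bad_pixel_rate: float = 0.002
    planted: tuple[PlantedGene, ...] = field(default_factory=lambda: (PlantedGene(),))

    def validate(self) -> None:
        if self.n_genes < 2:
            raise ValidationError("need at least two genes")
        if self.n_replicates < 4:
            raise ValidationError("need at least 4 biological replicas")
        if not 0 < self.probe_geometric_p <= 1:
            raise ValidationError("probe_geometric_p must be in (0, 1]")
        lo, hi = self.residual_sd_range
        if lo < 0 or hi < lo:
            raise ValidationError("invalid residual_sd_range")
        llo, lhi = self.loading_range
        if not (0 <= llo <= lhi < 1):
            raise ValidationError("loadings must lie in [0, 1)")
        if not 0 <= self.loaded_fraction <= 1:
            raise ValidationError("loaded_fraction must be a proportion")
        if self.probe_offset_sd < 0 or self.bad_pixel_rate < 0:
            raise ValidationError("SDs and rates must be non-negative")
        for pg in self.planted:
            if not 0 <= pg.index < self.n_genes:
                raise ValidationError(f"planted index {pg.index} out of range")
            if pg.loading is not None and not 0 <= pg.loading < 1:
                raise ValidationError("planted loading must lie in [0, 1)")
            if pg.n_probes is not None and not 1 <= pg.n_probes <= MAX_PROBES:
                raise ValidationError(f"planted n_probes must lie in 1..{MAX_PROBES}")


def _gene_rng(seed: int, tag: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed, tag, *key])


def gene_names(config: SyntheticConfig) -> list[str]:
    width = max(4, len(str(config.n_genes - 1)))
    return [f"G{i:0{width}d}" for i in range(config.n_genes)]


def gene_parameters(config: SyntheticConfig) -> pd.DataFrame:
    """Deterministic per-gene generative parameters (the ground truth).

    Columns: ``baseline_log2``, ``n_probes``, ``residual_sd``,
    ``loading``, ``factor_sd`` (β) and ``total_log2_sd``.  Derivable from
    the config alone; data generation consumes exactly these values.
    """
    config.validate()
    rows = []
    planted = {pg.index: pg for pg in config.planted}
    for i in range(config.n_genes):
        rng = _gene_rng(config.seed, _PARAMS, i)
        n_probes = min(int(rng.geometric(config.probe_geometric_p)), MAX_PROBES)
        baseline = rng.normal(0.0, config.baseline_log2_sd)
        sigma = rng.uniform(*config.residual_sd_range)
        loaded = rng.random() < config.loaded_fraction
        # balanced signs: loaded genes fluctuate in phase or in antiphase
        # with the factor, so the per-replicate median stays factor-neutral
        # (a one-signed factor would leak into the normalizer)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        loading = sign * rng.uniform(*config.loading_range) if loaded else 0.0
        if i in planted:
            pg = planted[i]
            baseline = math.log2(pg.mean_multiplier)
            if pg.residual_sd is not None:
                sigma = pg.residual_sd
            if pg.loading is not None:
                loading = pg.loading
            if pg.n_probes is not None:
                n_probes = pg.n_probes
        factor_sd = sigma * loading / math.sqrt(1.0 - loading**2)
        rows.append(
            (baseline, n_probes, sigma, loading, factor_sd,
             math.sqrt(factor_sd**2 + sigma**2))
        )
    return pd.DataFrame(
        rows,
        index=pd.Index(gene_names(config), name="gene"),
        columns=[
            "baseline_log2", "n_probes", "residual_sd",
            "loading", "factor_sd", "total_log2_sd",
        ],
    )


def generate_dataset(
    config: SyntheticConfig,
    condition_index: int = 0,
    label: str | None = None,
    baseline_shift_log2: np.ndarray | None = None,
) -> ExpressionDataset:
    """Generate one probe-level dataset (raw fg/bg/ok table).

    ``condition_index`` selects an independent noise stream while keeping
    the per-gene parameters fixed, so paired conditions share their
    generative law.  ``baseline_shift_log2`` (length n_genes) shifts gene
    baselines — the mechanism behind planted regulation.  Deterministic
    under a fixed config.
    """
    config.validate()
    params = gene_parameters(config)
    lam = config.n_replicates
    factor = _gene_rng(config.seed, _FACTOR, condition_index).standard_normal(lam)
    shift = (
        np.zeros(config.n_genes)
        if baseline_shift_log2 is None
        else np.asarray(baseline_shift_log2, float)
    )
    if shift.shape != (config.n_genes,):
        raise ValidationError("baseline_shift_log2 must have length n_genes")

    probe_ids: list[str] = []
    gene_col: list[str] = []
    fg_blocks: list[np.ndarray] = []
    bg_blocks: list[np.ndarray] = []
    ok_blocks: list[np.ndarray] = []
    for i, (gene, p) in enumerate(params.iterrows()):
        rng = _gene_rng(config.seed, _NOISE, condition_index, i)
        r = int(p["n_probes"])
        shared = p["baseline_log2"] + shift[i] + p["factor_sd"] * factor
        affinity = rng.normal(0.0, config.probe_offset_sd, r)
        noise = rng.normal(0.0, p["residual_sd"], (r, lam))
        log2_expr = shared[None, :] + affinity[:, None] + noise
        linear = np.exp2(log2_expr)
        bg = rng.uniform(*config.background_range, (r, lam))
        fg = config.intensity_scale * linear + bg
        ok = rng.random((r, lam)) >= config.bad_pixel_rate
        probe_ids += [f"{gene}_p{k + 1}" for k in range(r)]
        gene_col += [gene] * r
        fg_blocks.append(fg)
        bg_blocks.append(bg)
        ok_blocks.append(ok)

    # control spots exercise the QC path
    qc_rng = _gene_rng(config.seed, _QC, condition_index)
    n_controls = int(round(config.control_fraction * len(probe_ids)))
    if n_controls:
        probe_ids += [f"CTRL_{k + 1}" for k in range(n_controls)]
        gene_col += ["CONTROL"] * n_controls
        fg_blocks.append(qc_rng.uniform(100.0, 1000.0, (n_controls, lam)))
        bg_blocks.append(qc_rng.uniform(*config.background_range, (n_controls, lam)))
        ok_blocks.append(np.ones((n_controls, lam), bool))

    fg = np.vstack(fg_blocks)
    bg = np.vstack(bg_blocks)
    ok = np.vstack(ok_blocks)
    is_control = np.array([g == "CONTROL" for g in gene_col])
    probes = pd.DataFrame(index=pd.Index(probe_ids, name="probe_id"))
    probes["gene_id"] = gene_col
    probes["is_control"] = is_control
    for k in range(lam):
        probes[f"fg_{k + 1}"] = fg[:, k]
        probes[f"bg_{k + 1}"] = bg[:, k]
        probes[f"ok_{k + 1}"] = ok[:, k]
    return ExpressionDataset(
        condition=label or f"{config.condition}_{condition_index}",
        n_replicates=lam,
        probes=probes,
    )


def generate_paired_conditions(
    config: SyntheticConfig,
    regulated_fraction: float = 0.1,
    effect_log2_range: tuple[float, float] = (1.0, 2.0),
    labels: tuple[str, str] = ("normal", "cancer"),
) -> tuple[ExpressionDataset, ExpressionDataset, pd.DataFrame]:
    """Two conditions sharing a generative law, with planted regulation.

    Condition B clones A's per-gene parameters and multiplies a random
    subset's baseline by fold-changes drawn from ``effect_log2_range``
    (random direction).  Returns (A, B, truth) where ``truth`` has one
    row per gene with the signed planted log2 effect.
    """
    if not 0 <= regulated_fraction <= 1:
        raise ValidationError("regulated_fraction must be a proportion")
    lo, hi = effect_log2_range
    if lo < 0 or hi < lo:
        raise ValidationError("invalid effect_log2_range")
    rng = _gene_rng(config.seed, _EFFECTS)
    regulated = rng.random(config.n_genes) < regulated_fraction
    magnitude = rng.uniform(lo, hi, config.n_genes)
    sign = np.where(rng.random(config.n_genes) < 0.5, 1.0, -1.0)
    effect = np.where(regulated, sign * magnitude, 0.0)

    ds_a = generate_dataset(config, condition_index=0, label=labels[0])
    ds_b = generate_dataset(
        config, condition_index=1, label=labels[1], baseline_shift_log2=effect
    )
    truth = pd.DataFrame(
        {
            "gene": gene_names(config),
            "regulated": regulated,
            "effect_log2": effect,
        }
    )
    return ds_a, ds_b, truth


def crossed_cell_line_configs(
    seed: int, n_genes: int = 300
) -> tuple[SyntheticConfig, SyntheticConfig]:
    """Two "cell line" configs for the crossed transfection design.

    Four genes share the same elevated expression level in both lines;
    genes 0 and 1 are planted as strong (stable, highly loaded) in line A
    only, genes 2 and 3 in line B only — so each gene's GCH ordering
    flips between the lines while its abundance does not.  Generate line
    A with ``condition_index=0`` and line B with ``condition_index=1``
    and perturb each of the four genes in both lines to test whether the
    GCH hierarchy predicts where the consequences are larger.
    """
    strong = dict(mean_multiplier=5.0, residual_sd=0.02, loading=0.8, n_probes=8)
    # the decoy is a deliberately noisy, uncoordinated gene at the same
    # expression level — the low-GCH member of each transfected pair
    decoy = dict(mean_multiplier=5.0, residual_sd=0.5, loading=0.0, n_probes=2)
    planted_a = (
        PlantedGene(0, **strong), PlantedGene(1, **strong),
        PlantedGene(2, **decoy), PlantedGene(3, **decoy),
    )
    planted_b = (
        PlantedGene(0, **decoy), PlantedGene(1, **decoy),
        PlantedGene(2, **strong), PlantedGene(3, **strong),
    )
    return (
        SyntheticConfig(n_genes=n_genes, seed=seed, planted=planted_a,
                        condition="lineA"),
        SyntheticConfig(n_genes=n_genes, seed=seed, planted=planted_b,
                        condition="lineB"),
    )


def simulate_perturbation(
    dataset: ExpressionDataset, target: str, delta_log2: float
) -> ExpressionDataset:
    """Propagate a forced log2 shift of one gene through the correlation web.

    The target's log2 expression moves by δ; every other gene j moves by
    ρ_tj · δ · (s_j / s_t), the regression-slope response on the log2
    scale.  ρ is the Pearson correlation of gene-level log2 expression;
    the replicate SDs s are pooled over each gene's redundant probes
    (root mean square of the per-probe log2 replicate SDs, the same
    pooling the REV estimator uses), which keeps the slope stable for
    well-probed genes.  This propagation rule is the package's own
    minimal model of downstream consequences — real transfection data is
    the authoritative test; the rule only makes the GCH→consequence
    claim testable in software.  Returns a new dataset; the input is
    untouched.
    """
    if delta_log2 == 0:
        raise ValidationError("delta_log2 must be non-zero")
    if dataset.expression is None:
        raise DataError("run QC/normalization before simulating a perturbation")
    gene_level = dataset.gene_expression()
    if target not in gene_level.index:
        raise DataError(f"target gene {target!r} not quantified")
    logs = np.log2(gene_level.to_numpy(float))
    centered = logs - logs.mean(axis=1, keepdims=True)
    probe_logs = np.log2(dataset.expression.to_numpy(float))
    probe_var = probe_logs.var(axis=1, ddof=1)
    pooled = np.sqrt(
        pd.Series(probe_var, index=dataset.expression.index)
        .groupby(dataset.probes.loc[dataset.expression.index, "gene_id"])
        .mean()
        .sort_index()
        .reindex(gene_level.index)
        .to_numpy(float)
    )
    sd = pooled
    t_pos = gene_level.index.get_loc(target)
    if sd[t_pos] == 0:
        raise DataError("target has zero replicate variance; slope undefined")
    with np.errstate(invalid="ignore"):
        rho = (centered @ centered[t_pos]) / (
            np.linalg.norm(centered, axis=1) * np.linalg.norm(centered[t_pos])
        )
    rho = np.nan_to_num(rho)
    shift = rho * delta_log2 * sd / sd[t_pos]
    # numerical guard far beyond any biological response: keeps the
    # shifted intensities finite when the target SD is near zero
    shift = np.clip(shift, -64.0, 64.0)
    shift[t_pos] = delta_log2

    factors = pd.Series(np.exp2(shift), index=gene_level.index)
    probe_factors = dataset.probes.loc[dataset.expression.index, "gene_id"].map(
        factors
    ).fillna(1.0)
    expr = dataset.expression.mul(probe_factors.to_numpy(float), axis=0)
    return replace(dataset, expression=expr)


def perturbation_wpr(
    original: ExpressionDataset,
    perturbed: ExpressionDataset,
    epsilon: float = 0.05,
) -> float:
    """Transcriptome-wide WPR of a perturbation against its baseline.

    Scores the perturbed dataset ("cancer" role) against the original
    ("normal" role) with the whole quantified transcriptome as one gene
    set — the summary statistic of simulated-transfection consequences.
    """
    sum_p = rev_per_gene(perturbed, epsilon)
    sum_o = rev_per_gene(original, epsilon)
    common = sum_p.table.index.intersection(sum_o.table.index)
    sum_p.table = sum_p.table.loc[common]
    sum_o.table = sum_o.table.loc[common]
    records = regulation_calls(sum_p, sum_o, perturbed, original)
    everything = GeneSet("ALL", "whole transcriptome", tuple(common))
    return wpr(records, sum_o.table["mean_expression"], everything)
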