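"""Generator contracts: determinism, stream stability, parameter recovery,
planted regulation, perturbation propagation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gmr.errors import ValidationError
from gmr.qc import align_conditions, filter_probes, normalize_median
from gmr.regulation import regulation_calls
from gmr.stability import rev_per_gene
from gmr.synthetic import (
    PlantedGene,
    SyntheticConfig,
    gene_parameters,
    generate_dataset,
    generate_paired_conditions,
    simulate_perturbation,
)

from conftest import make_expression_dataset


def prepared(config, **kwargs):
    ds = generate_dataset(config, **kwargs)
    filtered, _ = filter_probes(ds)
    return normalize_median(filtered)


class TestGenerateDataset:
    def test_same_seed_bit_identical(self):
        config = SyntheticConfig(n_genes=40, seed=5)
        a = generate_dataset(config)
        b = generate_dataset(config)
        pd.testing.assert_frame_equal(a.probes, b.probes)

    def test_shapes_and_probe_counts_follow_config(self):
        config = SyntheticConfig(n_genes=120, seed=2)
        ds = generate_dataset(config)
        assert ds.n_genes == 120
        params = gene_parameters(config)
        counts = pd.Series({g: len(p) for g, p in ds.gene_index.items()})
        pd.testing.assert_series_equal(
            counts.sort_index(), params["n_probes"].sort_index(),
            check_names=False, check_dtype=False,
        )
        assert params["n_probes"].between(1, 28).all()

    def test_adding_genes_does_not_reshuffle_existing_ones(self):
        small = SyntheticConfig(n_genes=30, seed=9)
        large = SyntheticConfig(n_genes=45, seed=9)
        ds_small = generate_dataset(small)
        ds_large = generate_dataset(large)
        common = ds_small.probes.index
        cols = [c for c in ds_small.probes.columns]
        pd.testing.assert_frame_equal(
            ds_small.probes[cols], ds_large.probes.loc[common, cols]
        )

    def test_different_condition_index_changes_noise_not_structure(self):
        config = SyntheticConfig(n_genes=30, seed=9)
        a = generate_dataset(config, condition_index=0)
        b = generate_dataset(config, condition_index=1)
        assert list(a.probes.index) == list(b.probes.index)
        assert not np.allclose(
            a.probes["fg_1"].to_numpy(), b.probes["fg_1"].to_numpy()
        )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(n_genes=10, planted=(PlantedGene(index=10),)).validate()
        with pytest.raises(ValidationError):
            SyntheticConfig(residual_sd_range=(0.5, 0.1)).validate()

    def test_cv_recovers_configured_noise(self):
        # the pooled CV (REV with the chi-square correction divided out),
        # averaged over independent datasets to beat the lambda=4 estimator
        # noise, must track the configured per-gene total log2 SD
        from gmr.stability import chi2_midinterval_coefficient

        config = SyntheticConfig(n_genes=300, seed=21)
        params = gene_parameters(config)
        accumulated: dict[str, list[float]] = {}
        for condition_index in range(8):
            summary = rev_per_gene(prepared(config, condition_index=condition_index))
            coeff = summary.table["dof"].map(
                lambda r: chi2_midinterval_coefficient(int(r))
            )
            for gene, value in (summary.table["rev"] / coeff).items():
                accumulated.setdefault(gene, []).append(value)
        mean_cv = pd.Series({g: np.mean(v) for g, v in accumulated.items()})
        common = mean_cv.index.intersection(params.index)
        rho = stats.spearmanr(
            mean_cv.loc[common], params.loc[common, "total_log2_sd"]
        ).statistic
        assert rho >= 0.9

    def test_planted_gmr_has_minimum_rev_most_seeds(self):
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            config = SyntheticConfig(n_genes=500, seed=seed)
            summary = rev_per_gene(prepared(config))
            hits += summary.table["rev"].idxmin() == "G0000"
        assert hits / n_seeds >= 0.8


class TestPairedConditions:
    def test_truth_labels_cover_all_genes(self):
        config = SyntheticConfig(n_genes=50, seed=3)
        _, _, truth = generate_paired_conditions(config, 0.2)
        assert len(truth) == 50
        assert truth.loc[~truth["regulated"], "effect_log2"].eq(0).all()

    def test_zero_regulated_fraction_calls_mostly_nothing(self):
        config = SyntheticConfig(n_genes=150, seed=8, planted=())
        ds_n, ds_c, truth = generate_paired_conditions(config, 0.0)
        assert not truth["regulated"].any()
        a, _ = filter_probes(ds_c)
        b, _ = filter_probes(ds_n)
        a, b = align_conditions(normalize_median(a), normalize_median(b))
        sa, sb = rev_per_gene(a), rev_per_gene(b)
        common = sa.table.index.intersection(sb.table.index)
        sa.table, sb.table = sa.table.loc[common], sb.table.loc[common]
        records = regulation_calls(sa, sb, a, b)
        fpr = (records["call"] != "not_significant").mean()
        assert fpr <= 0.07

    def test_strong_stable_effects_are_recovered(self):
        # planted 2x+ effects on top of a low-noise background are called
        config = SyntheticConfig(
            n_genes=150, seed=4, planted=(),
            residual_sd_range=(0.05, 0.15), loaded_fraction=0.0,
        )
        ds_n, ds_c, truth = generate_paired_conditions(
            config, 0.2, effect_log2_range=(1.0, 2.0)
        )
        a, _ = filter_probes(ds_c)
        b, _ = filter_probes(ds_n)
        a, b = align_conditions(normalize_median(a), normalize_median(b))
        sa, sb = rev_per_gene(a), rev_per_gene(b)
        common = sa.table.index.intersection(sb.table.index)
        sa.table, sb.table = sa.table.loc[common], sb.table.loc[common]
        records = regulation_calls(sa, sb, a, b).set_index("gene")
        truth = truth.set_index("gene").loc[records.index]
        called = records["call"] != "not_significant"
        sensitivity = called[truth["regulated"]].mean()
        assert sensitivity >= 0.9
        # directions match the planted signs
        up = records.loc[truth["effect_log2"] > 0, "call"]
        assert (up[up != "not_significant"] == "up").all()


class TestSimulatePerturbation:
    def test_uncorrelated_genes_untouched(self):
        # B and C are exactly orthogonal to A after centering
        ds = make_expression_dataset(
            {
                "A": [list(np.exp2([1.0, 2.0, 3.0, 4.0]))],
                "B": [list(np.exp2([1.0, 2.0, 2.0, 1.0]))],
                "C": [list(np.exp2([2.0, 1.0, 1.0, 2.0]))],
            }
        )
        perturbed = simulate_perturbation(ds, "A", 2.0)
        np.testing.assert_allclose(
            perturbed.expression.loc["B_p1"], ds.expression.loc["B_p1"], rtol=1e-12
        )
        np.testing.assert_allclose(
            perturbed.expression.loc["A_p1"],
            4.0 * ds.expression.loc["A_p1"],
            rtol=1e-12,
        )

    def test_perfect_partner_with_equal_sd_shifts_by_delta(self):
        ds = make_expression_dataset(
            {
                "A": [list(np.exp2([1.0, 2.0, 3.0, 4.0]))],
                "B": [list(np.exp2([2.0, 3.0, 4.0, 5.0]))],  # rho=1, same SD
                "C": [list(np.exp2([1.0, 2.0, 2.0, 1.0]))],
            }
        )
        perturbed = simulate_perturbation(ds, "A", 1.5)
        np.testing.assert_allclose(
            perturbed.expression.loc["B_p1"],
            2.0**1.5 * ds.expression.loc["B_p1"],
            rtol=1e-12,
        )

    def test_zero_delta_rejected(self):
        ds = make_expression_dataset({"A": [[1, 2, 3, 4]], "B": [[2, 2, 3, 3]]})
        with pytest.raises(ValidationError):
            simulate_perturbation(ds, "A", 0.0)
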