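"""Statistical shape and determinism of the synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from genoconverge import qpcr
from genoconverge.eqtl import z_to_p
from genoconverge.simulate import (
    DeGene,
    PlantedLocus,
    SimConfig,
    gene_at,
    gene_names,
    sim_annotation,
    sim_ct,
    sim_edges,
    sim_eqtl,
    sim_expression,
    sim_gwas,
)


class TestSimGwas:
    def test_null_p_values_are_uniform_across_seeds(self):
        # KS vs Uniform(0,1) non-significant at 0.01 for >= 95/100 seeds
        rejections = 0
        for seed in range(100):
            cfg = SimConfig(seed=seed, n_snps=1000)
            p = sim_gwas(cfg)["p"].to_numpy()
            if stats.kstest(p, "uniform").pvalue < 0.01:
                rejections += 1
        assert rejections <= 5

    def test_same_seed_identical_tables(self):
        cfg = SimConfig(seed=7, planted_loci=(PlantedLocus(1_000_000, 6.0),))
        pd.testing.assert_frame_equal(sim_gwas(cfg), sim_gwas(cfg))

    def test_planted_cluster_is_co_significant(self):
        cfg = SimConfig(
            seed=3, ld_cluster_size=10,
            planted_loci=(PlantedLocus(2_000_000, 6.0, span_bp=20_000),),
        )
        table = sim_gwas(cfg)
        span = table[(table.pos >= 1_990_000) & (table.pos <= 2_010_000)]
        assert (span["p"] < 0.05).sum() >= 10

    def test_positions_sorted_and_inside_chromosome(self):
        cfg = SimConfig(seed=1, n_snps=500)
        table = sim_gwas(cfg)
        assert table["pos"].is_monotonic_increasing
        assert table["pos"].between(1, cfg.chrom_length_bp).all()

    def test_overlapping_planted_loci_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SimConfig(planted_loci=(PlantedLocus(1_000_000, 6.0),
                                    PlantedLocus(1_010_000, 5.0)))

    def test_locus_outside_chromosome_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            SimConfig(planted_loci=(PlantedLocus(5_000, 6.0),))


class TestSimExpression:
    def test_null_per_probe_rejection_near_alpha(self):
        cfg = SimConfig(seed=5, n_genes=334, probes_per_gene=3)  # 1002 probes
        from genoconverge.expression import probe_tests

        (ds,) = sim_expression(cfg, n_datasets=1)
        rate = np.mean([r.p < 0.05 for r in probe_tests(ds)])
        assert abs(rate - 0.05) < 4 * np.sqrt(0.05 * 0.95 / 1002)

    def test_planted_effect_shifts_case_means(self):
        hits = 0
        for seed in range(50):
            cfg = SimConfig(
                seed=seed, n_genes=10, probes_per_gene=2,
                de_genes=(DeGene("G0004", 1.5, (0, 1)),),
            )
            datasets = sim_expression(cfg, n_datasets=2)
            ok = True
            for ds in datasets:
                case = ds.groups == "case"
                probes = [p for p in ds.values.index if ds.probe_gene[p] == "G0004"]
                sub = ds.values.loc[probes]
                ok &= bool(
                    (sub.loc[:, case.values].mean(axis=1)
                     > sub.loc[:, ~case.values].mean(axis=1)).all()
                )
            hits += ok
        assert hits >= 48  # >= 95% of seeds

    def test_probe_count_and_mapping(self):
        cfg = SimConfig(seed=0, n_genes=3, probes_per_gene=1)
        datasets = sim_expression(cfg, n_datasets=2)
        for ds in datasets:
            assert len(ds.values) == 3
            assert set(ds.probe_gene.loc[ds.values.index]) == set(gene_names(cfg))

    def test_unknown_de_gene_rejected(self):
        cfg = SimConfig(n_genes=5, de_genes=(DeGene("NOPE", 1.0),))
        with pytest.raises(ValueError, match="NOPE"):
            sim_expression(cfg, n_datasets=2)


class TestSimEqtl:
    def test_p_consistent_with_z_by_construction(self):
        cfg = SimConfig(seed=2)
        table = sim_eqtl(sim_gwas(cfg), gene_names(cfg), cfg)
        for row in table.itertuples():
            assert row.p == pytest.approx(z_to_p(row.z), rel=1e-12)

    def test_planted_rows_appended(self):
        cfg = SimConfig(seed=2)
        table = sim_eqtl(sim_gwas(cfg), gene_names(cfg), cfg,
                         planted=[("rs000001", "G0001", -10.92)])
        planted = table[(table.snp_id == "rs000001") & (table.gene == "G0001")]
        assert len(planted) == 1 and planted["z"].iloc[0] == -10.92

    def test_deterministic(self):
        cfg = SimConfig(seed=9)
        snps = sim_gwas(cfg)
        pd.testing.assert_frame_equal(
            sim_eqtl(snps, gene_names(cfg), cfg),
            sim_eqtl(snps, gene_names(cfg), cfg),
        )


class TestSimCt:
    def test_null_shift_rejects_at_nominal_rate(self):
        rejections = 0
        for seed in range(200):
            cfg = SimConfig(seed=seed, ct_shift=0.0, n_case=10, n_control=10)
            ct = sim_ct(cfg, targets=["TGT"])
            rel = qpcr.relative_expression(ct, "TGT", ["GAPDH", "ACT"])
            if qpcr.compare_groups(rel)["p_t"] < 0.05:
                rejections += 1
        # binomial 4-sigma band around 5% of 200
        assert abs(rejections / 200 - 0.05) < 4 * np.sqrt(0.05 * 0.95 / 200)

    def test_one_cycle_shift_doubles_case_expression(self):
        ratios = []
        for seed in range(50):
            cfg = SimConfig(seed=seed, ct_shift=1.0)
            ct = sim_ct(cfg, targets=["TGT"])
            rel = qpcr.relative_expression(ct, "TGT", ["GAPDH", "ACT"])
            means = rel.groupby("group")["value"].mean()
            ratios.append(means["case"] / means["control"])
        mean = np.mean(ratios)
        half_ci = 1.96 * np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert mean - half_ci <= 2.0 <= mean + half_ci or abs(mean - 2.0) < 0.05

    def test_housekeeping_stable_across_groups(self):
        cfg = SimConfig(seed=4, ct_shift=1.5)
        ct = sim_ct(cfg, targets=["TGT"])
        hk = ct[ct.gene == "GAPDH"].groupby("group")["ct"].mean()
        assert abs(hk["case"] - hk["control"]) < 0.2

    def test_deterministic(self):
        cfg = SimConfig(seed=12)
        pd.testing.assert_frame_equal(
            sim_ct(cfg, ["TGT"]), sim_ct(cfg, ["TGT"])
        )

    def test_empty_housekeeping_rejected(self):
        with pytest.raises(ValueError, match="housekeeping"):
            sim_ct(SimConfig(), ["TGT"], housekeeping=[])


class TestAnnotation:
    def test_genes_tile_without_overlap(self):
        cfg = SimConfig(n_genes=50)
        ann = sim_annotation(cfg)
        assert len(ann) == 50
        assert (ann["end"] > ann["start"]).all()
        assert (ann["start"].to_numpy()[1:] > ann["end"].to_numpy()[:-1]).all()

    def test_gene_at_center(self):
        cfg = SimConfig(n_genes=100)
        ann = sim_annotation(cfg)
        row = ann.iloc[49]
        center = (row["start"] + row["end"]) // 2
        assert gene_at(cfg, int(center)) == row["symbol"]


class TestSimEdges:
    def test_de_genes_connected_by_coexpression(self):
        cfg = SimConfig(seed=1, de_genes=(DeGene("G0001", 1.0), DeGene("G0002", 1.0)))
        edges = sim_edges(cfg)
        pair = edges[(edges.gene_a == "G0001") & (edges.gene_b == "G0002")]
        assert len(pair) == 1 and pair["coexpression"].iloc[0] >= 0.3

    def test_scores_in_unit_interval_and_deterministic(self):
        cfg = SimConfig(seed=6)
        edges = sim_edges(cfg)
        for ch in ("coexpression", "experimental", "combined"):
            assert edges[ch].between(0, 1).all()
        pd.testing.assert_frame_equal(edges, sim_edges(cfg))
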