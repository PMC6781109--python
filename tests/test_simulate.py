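import numpy as np
import pandas as pd
import pytest

from gbmnoise import introns as intr, noise
from gbmnoise.config import SimConfig
from gbmnoise import scenarios
from gbmnoise.simulate import (
    assign_classes,
    simulate_all,
    simulate_expression,
    simulate_features,
    simulate_genome,
    simulate_methylomes,
    simulate_reads,
)


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_genes=0)
        with pytest.raises(ValueError):
            SimConfig(n_cells=1)
        with pytest.raises(ValueError):
            SimConfig(class_proportions={"gbM": 1.0})
        with pytest.raises(ValueError):
            SimConfig(retention_fraction={"gbM": 1.5, "unmethylated": 0.1,
                                          "highly_methylated_non_gbM": 0.1,
                                          "ambiguous": 0.1})

    def test_yaml_round_trip(self, tmp_path, small_config):
        p = tmp_path / "cfg.yaml"
        small_config.to_yaml(p)
        back = SimConfig.from_yaml(p)
        assert back == small_config

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown config keys"):
            SimConfig.from_dict({"not_a_knob": 1})


class TestGenome:
    def test_deterministic_under_seed(self, small_config):
        g1 = simulate_genome(small_config)
        g2 = simulate_genome(small_config)
        assert g1 == g2

    def test_gene_structure_bounds(self, small_config):
        for g in simulate_genome(small_config):
            assert 1 <= len(g.exons) <= small_config.max_exons
            assert g.exons[0][0] == g.start and g.exons[-1][1] == g.end
            assert g.length >= small_config.min_gene_length

    def test_zero_overlap_fraction_leaves_all_nonoverlapping(self):
        cfg = SimConfig(seed=4, n_genes=200, overlap_fraction=0.0)
        genes = simulate_genome(cfg)
        assert len(intr.flag_overlapping_genes(genes)) == len(genes)

    def test_overlap_fraction_plants_overlaps(self):
        cfg = SimConfig(seed=4, n_genes=200, overlap_fraction=0.3)
        genes = simulate_genome(cfg)
        assert len(intr.flag_overlapping_genes(genes)) < len(genes)


class TestMethylomes:
    def test_extreme_rates(self, small_config):
        cfg = small_config.replace(
            overlap_fraction=0.0,
            meth_rates={
                "gbM": {"CG": 1.0, "CHG": 1.0, "CHH": 1.0},
                "unmethylated": {"CG": 0.0, "CHG": 0.0, "CHH": 0.0},
                "highly_methylated_non_gbM": {"CG": 1.0, "CHG": 1.0, "CHH": 1.0},
            },
            ambiguous_cg_range=(0.0, 0.0),
            ambiguous_non_cg_rate=0.0,
        )
        genes = simulate_genome(cfg)
        rep1, _rep2, truth = simulate_methylomes(cfg, genes)
        checked = 0
        for g, cls in zip(genes, truth["class"]):
            sub = rep1[(rep1["chrom"].astype(str) == g.chrom)
                       & rep1["pos"].between(g.start, g.end)]
            if len(sub) == 0:
                continue
            if cls in ("unmethylated", "ambiguous"):
                assert (sub["meth"] == 0).all()  # rate 0 -> no methylated call
                checked += 1
            elif cls == "gbM":
                assert (sub["unmeth"] == 0).all()  # rate 1 -> all methylated
                checked += 1
        assert checked > 50

    def test_replicates_share_sites_but_not_counts(self, small_config):
        genes = simulate_genome(small_config)
        rep1, rep2, _ = simulate_methylomes(small_config, genes)
        # same genome: same site positions modulo coverage-zero drops
        assert not rep1.equals(rep2)
        common = set(map(tuple, rep1[["pos", "context"]].to_numpy())) & set(
            map(tuple, rep2[["pos", "context"]].to_numpy())
        )
        assert len(common) > 0.8 * min(len(rep1), len(rep2))

    def test_deterministic_under_seed(self, small_config):
        genes = simulate_genome(small_config)
        a1, a2, _ = simulate_methylomes(small_config, genes)
        b1, b2, _ = simulate_methylomes(small_config, genes)
        pd.testing.assert_frame_equal(a1, b1)
        pd.testing.assert_frame_equal(a2, b2)


class TestFeatures:
    def test_null_correlations_near_zero(self):
        cfg = SimConfig(seed=9, n_genes=5000,
                        gbm_feature_corr={k: 0.0 for k in
                                          SimConfig().gbm_feature_corr})
        genes = simulate_genome(cfg)
        truth = assign_classes(cfg, genes)
        feats = simulate_features(cfg, truth)
        g = truth["is_gbm"].to_numpy()
        for col in ("gene_length", "ka_ks", "module_size", "expression_breadth"):
            r = np.corrcoef(g, np.log(feats[col].astype(float) + 1))[0, 1]
            assert abs(r) < 0.05

    def test_planted_length_correlation_recovered(self):
        cfg = SimConfig(seed=9, n_genes=5000)  # planted corr 0.4
        genes = simulate_genome(cfg)
        truth = assign_classes(cfg, genes)
        r = np.corrcoef(truth["is_gbm"], np.log(truth["gene_length"]))[0, 1]
        assert r == pytest.approx(0.4, abs=0.05)

    def test_deterministic_under_seed(self, small_config):
        genes = simulate_genome(small_config)
        t1 = assign_classes(small_config, genes)
        f1 = simulate_features(small_config, t1)
        t2 = assign_classes(small_config, genes)
        f2 = simulate_features(small_config, t2)
        pd.testing.assert_frame_equal(f1, f2)

    def test_correlation_cap_enforced(self):
        corr = dict(SimConfig().gbm_feature_corr)
        corr["gene_length"] = 0.95
        with pytest.raises(ValueError, match="cap"):
            SimConfig(gbm_feature_corr=corr)


class TestExpression:
    def _truth(self, cfg):
        genes = simulate_genome(cfg)
        truth = assign_classes(cfg, genes)
        simulate_features(cfg, truth)
        return genes, truth

    def test_deterministic_under_seed(self, small_config):
        _, truth1 = self._truth(small_config)
        m1 = simulate_expression(small_config, truth1)
        _, truth2 = self._truth(small_config)
        m2 = simulate_expression(small_config, truth2)
        pd.testing.assert_frame_equal(m1, m2)

    def test_unit_multiplier_no_dropout_gives_fstar_one(self):
        cfg = scenarios.multiplier_recovery(3, n_genes=2000).replace(
            multiplier_high_fraction=0.0
        )
        _, truth = self._truth(cfg)
        mat = simulate_expression(cfg, truth)
        table, _ = noise.build_noise_table(mat)
        assert 0.8 <= table["F_star"].median() <= 1.25

    def test_detection_probability_zero_silences_gene(self):
        cfg = SimConfig(seed=2, n_genes=100, detect_b0=-800.0, detect_b_mu=0.0,
                        detect_b_len=0.0, detect_b_noise=0.0, detect_b_gbm=0.0)
        _, truth = self._truth(cfg)
        mat = simulate_expression(cfg, truth)
        assert (mat.to_numpy() == 0).all()
        assert (noise.expression_consistency(mat) == 0).all()

    def test_moment_preservation_under_dropout(self):
        """Zero inflation must not move a gene's expected mean/variance:
        compare moments with detection on vs off at matched truth."""
        base = SimConfig(seed=6, n_genes=1500,
                         variance_trend=scenarios.MODERATE_TREND)
        on = base
        off = base.replace(dropout_enabled=False)
        _, t_on = self._truth(on)
        _, t_off = self._truth(off)
        m_on = simulate_expression(on, t_on)
        m_off = simulate_expression(off, t_off)
        # per-gene expectations are equal, so large-sample means agree
        assert m_on.to_numpy().mean() == pytest.approx(
            m_off.to_numpy().mean(), rel=0.1
        )
        mu_on, var_on = noise.mean_variance(m_on)
        mu_off, var_off = noise.mean_variance(m_off)
        assert np.median(var_on) == pytest.approx(np.median(var_off), rel=0.25)


class TestReads:
    def _dataset(self, cfg):
        genes = simulate_genome(cfg)
        truth = assign_classes(cfg, genes)
        simulate_features(cfg, truth)
        mat = simulate_expression(cfg, truth)
        return genes, truth, mat

    def test_retention_zero_means_no_intronic_reads(self, small_config):
        cfg = small_config.replace(
            retention_fraction={k: 0.0 for k in small_config.retention_fraction},
            overlap_fraction=0.0,
        )
        genes, truth, mat = self._dataset(cfg)
        reads = simulate_reads(cfg, genes, mat, truth)
        rows = intr.count_reads(reads, genes)
        assert rows["intron_reads"].sum() == 0

    def test_retention_one_means_all_intronic_for_intron_genes(self, small_config):
        cfg = small_config.replace(
            retention_fraction={k: 1.0 for k in small_config.retention_fraction},
            overlap_fraction=0.0,
        )
        genes, truth, mat = self._dataset(cfg)
        reads = simulate_reads(cfg, genes, mat, truth)
        rows = intr.count_reads(reads, genes)
        with_introns = rows["intron_number"] > 0
        # genes with usable introns receive no purely-exonic reads
        junction_free = rows.loc[with_introns]
        assert (junction_free["intron_reads"] >= junction_free["exon_reads"]).all()

    def test_reads_lie_inside_their_gene_features(self, small_config):
        cfg = small_config.replace(overlap_fraction=0.0)
        genes, truth, mat = self._dataset(cfg)
        reads = simulate_reads(cfg, genes, mat, truth)
        assert ((reads["end"] - reads["start"] + 1) == cfg.read_length).all()
        # every read falls fully inside one gene span
        rows = intr.count_reads(reads, genes)
        assert rows["total_reads"].sum() >= len(reads)

    def test_deterministic_under_seed(self, small_config):
        genes, truth, mat = self._dataset(small_config)
        r1 = simulate_reads(small_config, genes, mat, truth)
        genes, truth, mat = self._dataset(small_config)
        r2 = simulate_reads(small_config, genes, mat, truth)
        pd.testing.assert_frame_equal(r1, r2)

    def test_invalid_retention_rejected(self, small_config):
        genes, truth, mat = self._dataset(small_config)
        bad = dict(small_config.retention_fraction)
        bad["gbM"] = 1.5
        cfg = small_config.replace()
        cfg.retention_fraction = bad  # bypass construction-time validation
        with pytest.raises(ValueError):
            simulate_reads(cfg, genes, mat, truth)


class TestSimulateAll:
    def test_byte_identical_outputs_for_same_seed(self, tmp_path, small_config):
        from gbmnoise import iodata

        ds1 = simulate_all(small_config)
        ds2 = simulate_all(small_config)
        p1, p2 = tmp_path / "a.gff3", tmp_path / "b.gff3"
        iodata.write_gff3(p1, ds1.genes)
        iodata.write_gff3(p2, ds2.genes)
        assert p1.read_bytes() == p2.read_bytes()
        pd.testing.assert_frame_equal(ds1.matrix, ds2.matrix)
        pd.testing.assert_frame_equal(ds1.truth, ds2.truth)
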