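"""Tests for the synthetic data generators."""

import numpy as np
import pandas as pd
import pytest

from erydeconv import (
    GeneCoords,
    SimulationConfig,
    factorial_design,
    make_stage_table_fixture,
    simulate_cohorts,
    simulate_counts,
    simulate_eqtl_expression,
    simulate_genotypes,
    simulate_pbmc,
    two_group_design,
)


def small_coords(n=3):
    starts = np.arange(n) * 1_000_000 + 500_000
    return GeneCoords(pd.DataFrame(
        {"chrom": "chr1", "start": starts, "end": starts + 20_000},
        index=[f"G{i}" for i in range(n)]))


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=0)
        with pytest.raises(ValueError):
            SimulationConfig(maf=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(frac_de=1.5)

    def test_streams_are_independent(self):
        cfg = SimulationConfig(seed=3)
        a = cfg.rng("counts").random(5)
        b = cfg.rng("pbmc").random(5)
        assert not np.allclose(a, b)

    def test_stream_reproducible(self):
        cfg = SimulationConfig(seed=3)
        assert np.allclose(cfg.rng("counts").random(5),
                           SimulationConfig(seed=3).rng("counts").random(5))


class TestSimulateCounts:
    def test_deterministic(self):
        cfg = SimulationConfig(seed=7, n_genes=50)
        cm1, t1 = simulate_counts(cfg)
        cm2, t2 = simulate_counts(SimulationConfig(seed=7, n_genes=50))
        assert cm1.counts.equals(cm2.counts)
        assert t1.de_gene_ids == t2.de_gene_ids

    def test_shapes_and_classes(self):
        cfg = SimulationConfig(seed=1, n_genes=100, frac_de=0.2, frac_interaction=0.1)
        cm, truth = simulate_counts(cfg, factorial_design(4))
        assert cm.counts.shape == (100, 16)
        assert len(truth.de_gene_ids["shared"]) == 20
        assert len(truth.de_gene_ids["sca_specific"]) == 10
        assert not truth.de_gene_ids["shared"] & truth.de_gene_ids["sca_specific"]

    def test_planted_effect_moves_means(self):
        cfg = SimulationConfig(seed=2, n_genes=200, effect_log2fc=2.0,
                               n_samples_per_group=40, dispersion=0.05)
        cm, truth = simulate_counts(cfg)
        dis = cm.samples["disease"].to_numpy() == 1
        up = sorted(truth.de_gene_ids["up"])
        ratio = (cm.counts.loc[up].to_numpy()[:, dis].mean(axis=1) + 0.5) / \
                (cm.counts.loc[up].to_numpy()[:, ~dis].mean(axis=1) + 0.5)
        assert np.median(ratio) > 2.5  # planted 4-fold, allow sampling noise

    def test_poisson_limit_moments(self):
        cfg = SimulationConfig(seed=4, n_genes=300, dispersion=0.0, frac_de=0.0,
                               n_samples_per_group=100)
        cm, _ = simulate_counts(cfg)
        from erydeconv import estimate_size_factors
        sf = estimate_size_factors(cm.counts).to_numpy()
        x = cm.counts.to_numpy(float) / sf  # remove depth variation
        # for Poisson, var(x/sf)/mean(x/sf) ~ E[1/sf]; NB with phi=0.1 adds ~0.1 mu
        m = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        big = m > 50
        assert np.median(v[big] / m[big]) == pytest.approx(1.0, abs=0.25)


class TestSimulateGenotypes:
    def test_hwe_and_maf(self):
        cfg = SimulationConfig(seed=5, maf=0.29)
        gm, _ = simulate_genotypes(cfg, small_coords(), n_samples=4000,
                                   snps_per_gene=2, n_decoys=0)
        d = gm.dosages.to_numpy()
        af = d.mean(axis=1) / 2.0
        assert np.allclose(af, 0.29, atol=0.03)
        # heterozygosity at HWE: 2 p (1-p)
        het = (d == 1).mean(axis=1)
        assert np.allclose(het, 2 * 0.29 * 0.71, atol=0.03)

    def test_snps_within_window_and_decoys_outside(self):
        cfg = SimulationConfig(seed=6)
        coords = small_coords(2)
        gm, _ = simulate_genotypes(cfg, coords, n_samples=20, snps_per_gene=4,
                                   n_decoys=3, window_bp=100_000)
        tab = coords.table
        for snp, rec in gm.info.iterrows():
            near = ((rec["pos"] >= tab["start"] - 100_000)
                    & (rec["pos"] <= tab["end"] + 100_000)).any()
            if snp.startswith("rs_decoy"):
                assert not near, snp
            else:
                assert near, snp

    def test_planted_eqtl_recorded(self):
        cfg = SimulationConfig(seed=7, effect_log2fc=0.3)
        gm, truth = simulate_genotypes(cfg, small_coords(), n_samples=30,
                                       n_eqtl_genes=2)
        assert len(truth.true_eqtl) == 2
        for gene, snp, beta in truth.true_eqtl:
            assert snp in gm.info.index
            assert beta == pytest.approx(0.3)

    def test_eqtl_expression_carries_interaction(self):
        cfg = SimulationConfig(seed=8, effect_log2fc=1.0, noise_sd=0.1)
        coords = small_coords()
        gm, truth = simulate_genotypes(cfg, coords, n_samples=500, n_eqtl_genes=1)
        expr, z = simulate_eqtl_expression(cfg, gm, truth, list(coords.table.index))
        gene, snp, beta = truth.true_eqtl[0]
        dose = gm.dosages.loc[snp].to_numpy()
        y = expr.values.loc[gene].to_numpy()
        X = np.column_stack([np.ones_like(y), z, dose, z * dose])
        bhat = np.linalg.lstsq(X, y, rcond=None)[0]
        assert bhat[3] == pytest.approx(beta, abs=0.1)


class TestSimulatePbmc:
    def test_phenotype_columns_and_ranges(self):
        cfg = SimulationConfig(seed=9, n_genes=40)
        expr, ph, truth = simulate_pbmc(cfg, n_samples=400)
        t = ph.table
        for col in ("hgb", "hct", "retic_pct", "hydroxyurea", "transfused",
                    "age", "sex"):
            assert col in t.columns
        assert t["hgb"].mean() == pytest.approx(86, abs=3)
        assert t["hgb"].std() == pytest.approx(14, abs=2)
        assert set(t["transfused"].unique()) <= {0, 1}
        assert expr.values.shape == (40, 400)

    def test_markers_track_latent_fraction(self):
        cfg = SimulationConfig(seed=10, n_genes=30)
        expr, ph, truth = simulate_pbmc(cfg, n_samples=300)
        z = truth.extras["true_signature"]
        for m in truth.extras["marker_ids"][:4]:
            r = np.corrcoef(expr.values.loc[m], z)[0, 1]
            assert r > 0.8

    def test_interaction_beta_recorded(self):
        cfg = SimulationConfig(seed=11, n_genes=120, effect_log2fc=0.05)
        _, _, truth = simulate_pbmc(cfg, n_samples=50)
        planted = truth.de_gene_ids["interaction"]
        assert planted
        assert np.allclose(truth.true_interaction_beta[sorted(planted)], 0.05)
        nulls = truth.true_interaction_beta.drop(sorted(planted))
        assert np.allclose(nulls, 0.0)


class TestSimulateCohorts:
    def test_sizes_and_columns(self):
        cohorts = simulate_cohorts(SimulationConfig(seed=12))
        assert [len(ct.table) for ct, _ in cohorts] == [399, 207, 168]
        assert [ct.name for ct, _ in cohorts] == ["Walk-PHaSST", "PUSH", "UIC"]
        for ct, _ in cohorts:
            assert set(ct.table.columns) >= {"outcome", "dosage", "age", "sex",
                                             "alpha_thal_copies"}
            assert set(ct.table["outcome"].unique()) <= {0, 1}

    def test_null_or_gives_flat_risk(self):
        cohorts = simulate_cohorts(SimulationConfig(seed=13, planted_or=1.0),
                                   n_per_cohort=(5000,), names=("big",))
        t = cohorts[0][0].table
        by_dose = t.groupby(t["dosage"].round())["outcome"].mean()
        assert by_dose.max() - by_dose.min() < 0.06


class TestStageFixture:
    def test_rates_and_invariant(self):
        cfg = SimulationConfig(seed=14)
        table, de_dir = make_stage_table_fixture(cfg, n_genes=4000)
        t = table.table
        assert len(t) == 4000
        for tr in table.transitions:
            sig = t[f"significant_{tr}"]
            d = t[f"direction_{tr}"]
            assert ((d != 0) == sig).all()  # direction 0 iff not significant
        # planted concordance close to requested rates
        for tr, rate in zip(table.transitions, (0.82, 0.83, 0.70, 0.52)):
            d = t[f"direction_{tr}"]
            ev = d != 0
            conc = (d[ev] == de_dir[ev]).mean()
            assert conc == pytest.approx(rate, abs=0.04)

    def test_directions_match_gene_ids(self):
        table, de_dir = make_stage_table_fixture(SimulationConfig(seed=15), n_genes=50)
        assert list(de_dir.index) == list(table.gene_ids)
        assert set(de_dir.unique()) <= {-1, 1}


class TestDesigns:
    def test_two_group(self):
        d = two_group_design(3)
        assert list(d["disease"]) == [0, 0, 0, 1, 1, 1]

    def test_factorial(self):
        d = factorial_design(2)
        assert len(d) == 8
        assert sorted(map(tuple, d[["disease", "population"]].to_numpy().tolist())) \
            == [[0, 0]] * 0 + sorted([(0, 0), (0, 0), (1, 0), (1, 0),
                                      (0, 1), (0, 1), (1, 1), (1, 1)])
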