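"""Tests for the negative-binomial differential-expression stage."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import erydeconv as e
from erydeconv import diffexpr
from erydeconv.containers import CountMatrix


def poisson_oracle(y, X, sf):
    """statsmodels Poisson GLM with a size-factor offset, natural-log scale."""
    fit = sm.GLM(np.asarray(y, float), np.asarray(X, float),
                 family=sm.families.Poisson(),
                 offset=np.log(np.asarray(sf, float))).fit()
    return fit.params


class TestSizeFactors:
    def test_median_of_ratios_by_hand(self):
        counts = pd.DataFrame({"S1": [10, 100, 4], "S2": [20, 200, 8]},
                              index=["g1", "g2", "g3"])
        sf = diffexpr.estimate_size_factors(counts)
        # geometric reference per gene; ratios are c/ref; S2 doubles S1
        assert sf["S2"] / sf["S1"] == pytest.approx(2.0)
        # normalized to geometric mean one
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            diffexpr.estimate_size_factors(pd.DataFrame({"S1": [0], "S2": [0]}))


class TestNbFitPoissonLimit:
    def test_coefficients_match_statsmodels(self):
        rng = np.random.default_rng(21)
        design = diffexpr.design_matrix(e.two_group_design(8))
        sf = pd.Series(rng.lognormal(0, 0.2, size=16), index=design.index)
        for _ in range(5):
            mu = 50 * sf.to_numpy() * np.exp(0.7 * design["disease"].to_numpy())
            y = pd.Series(rng.poisson(mu), index=design.index)
            fit = diffexpr.fit_nb_gene(y, design, sf, dispersion=1e-10)
            oracle = poisson_oracle(y, design, sf)
            # package coefficients are on the log2 scale
            np.testing.assert_allclose(fit.coef.to_numpy() * np.log(2.0),
                                       oracle, atol=1e-6)

    def test_loglik_matches_poisson(self):
        rng = np.random.default_rng(22)
        design = diffexpr.design_matrix(e.two_group_design(6))
        sf = pd.Series(np.ones(12), index=design.index)
        y = pd.Series(rng.poisson(30, size=12), index=design.index)
        fit = diffexpr.fit_nb_gene(y, design, sf, dispersion=1e-12)
        res = sm.GLM(y.to_numpy(float), design.to_numpy(float),
                     family=sm.families.Poisson()).fit()
        assert fit.loglik == pytest.approx(res.llf, abs=1e-4)


class TestDispersion:
    def test_recovers_planted_dispersion(self):
        rng = np.random.default_rng(23)
        design = diffexpr.design_matrix(e.two_group_design(100))
        sf = pd.Series(np.ones(200), index=design.index)
        phi = 0.2
        mu = 100.0
        y = rng.negative_binomial(1 / phi, 1 / (1 + phi * mu), size=200)
        est = diffexpr.estimate_dispersion(y.astype(float),
                                           design.to_numpy(float),
                                           np.zeros(200))
        assert est == pytest.approx(phi, rel=0.35)

    def test_tagwise_shrinks_toward_common(self):
        cfg = e.SimulationConfig(seed=24, n_genes=150, frac_de=0.0)
        cm, _ = e.simulate_counts(cfg)
        design = diffexpr.design_matrix(cm.samples)
        sf = diffexpr.estimate_size_factors(cm.counts)
        tag = diffexpr.estimate_dispersions_tagwise(cm.counts, design, sf)
        assert (tag > 0).all()
        # generator draws phi log-normal around 0.1
        assert np.median(tag) == pytest.approx(0.1, rel=0.5)


class TestLrt:
    def test_identical_models_give_zero(self):
        rng = np.random.default_rng(25)
        design = diffexpr.design_matrix(e.two_group_design(5))
        sf = pd.Series(np.ones(10), index=design.index)
        y = pd.Series(rng.poisson(40, 10), index=design.index)
        full = diffexpr.fit_nb_gene(y, design, sf, dispersion=0.1)
        reduced = diffexpr.fit_nb_gene(y, design.drop(columns=["disease"]), sf,
                                       dispersion=0.1)
        stat, p = diffexpr.lrt(full, reduced)
        assert stat >= 0 and 0 <= p <= 1

    def test_requires_nested_models(self):
        rng = np.random.default_rng(26)
        design = diffexpr.design_matrix(e.two_group_design(5))
        sf = pd.Series(np.ones(10), index=design.index)
        y = pd.Series(rng.poisson(40, 10), index=design.index)
        full = diffexpr.fit_nb_gene(y, design, sf, dispersion=0.1)
        with pytest.raises(ValueError):
            diffexpr.lrt(full, full)  # same column set, no df difference

    def test_power_on_planted_effect(self):
        cfg = e.SimulationConfig(seed=27, n_genes=100, effect_log2fc=2.0,
                                 frac_de=0.2, n_samples_per_group=8)
        cm, truth = e.simulate_counts(cfg)
        res = diffexpr.run_de(cm)
        planted = truth.de_gene_ids["up"] | truth.de_gene_ids["down"]
        hit = res.loc[sorted(planted), "q"] < 0.05
        assert hit.mean() > 0.8
        # directions match the planted signs
        up_dir = res.loc[sorted(truth.de_gene_ids["up"]), "direction"]
        assert (up_dir == 1).mean() > 0.9


class TestDesignMatrix:
    def test_batch_dummies(self):
        s = e.two_group_design(3)
        s["batch"] = ["a", "a", "b", "b", "c", "c"]
        X = diffexpr.design_matrix(s)
        assert "batch_b" in X.columns and "batch_c" in X.columns
        assert "batch_a" not in X.columns

    def test_interaction_requires_population(self):
        with pytest.raises(ValueError):
            diffexpr.design_matrix(e.two_group_design(3), interaction=True)

    def test_collinear_rejected(self):
        s = e.factorial_design(2)
        s["batch"] = np.where(s["population"] == 1, "x", "y")
        with pytest.raises(ValueError, match="collinear"):
            diffexpr.design_matrix(s)

    def test_constant_columns_dropped(self):
        s = e.factorial_design(2)
        sub = s[s["population"] == 1]
        X = diffexpr.design_matrix(sub)
        assert "population" not in X.columns


class TestClassification:
    @staticmethod
    def frame(q, p, direction):
        idx = [f"g{i}" for i in range(len(q))]
        return pd.DataFrame({"q": q, "p": p, "direction": direction}, index=idx)

    def test_rule_table(self):
        #        shared  sca_sp  ce_only int_only null
        sca = self.frame([0.01, 0.01, 0.50, 0.50, 0.50],
                         [0.001, 0.001, 0.40, 0.40, 0.40],
                         [1, 1, 0, 0, 0])
        ce = self.frame([0.01, 0.80, 0.01, 0.80, 0.80],
                        [0.001, 0.90, 0.001, 0.60, 0.60],
                        [1, 0, -1, 0, 0])
        inter = self.frame([0.90, 0.01, 0.90, 0.01, 0.90],
                           [0.80, 0.001, 0.80, 0.001, 0.80],
                           [0, 1, 0, 1, 0])
        cls = e.classify_genes(sca, ce, inter)
        assert list(cls["gene_class"]) == [
            "shared", "sca_specific", "ce_only", "interaction_only", "null"]

    def test_shared_requires_same_direction(self):
        sca = self.frame([0.01], [0.001], [1])
        ce = self.frame([0.01], [0.001], [-1])
        inter = self.frame([0.9], [0.8], [0])
        assert e.classify_genes(sca, ce, inter)["gene_class"].iloc[0] != "shared"

    def test_universe_mismatch_rejected(self):
        sca = self.frame([0.01], [0.001], [1])
        ce = self.frame([0.01, 0.5], [0.001, 0.4], [1, 0])
        with pytest.raises(ValueError, match="universe"):
            e.classify_genes(sca, ce, ce)
        with pytest.raises(ValueError, match="universe"):
            e.classify_genes(ce, ce, sca)

    def test_summary_decomposition(self):
        cls = pd.DataFrame({
            "gene_class": ["sca_specific"] * 5 + ["shared", "null"],
            "direction": [1, 1, 1, -1, -1, 1, 0],
        })
        s = e.classification_summary(cls)
        assert s["n_sca_specific"] == 5
        assert s["n_sca_specific_up"] == 3
        assert s["n_sca_specific_down"] == 2
        assert s["n_sca_specific_total"] == 5


class TestRunDe:
    def test_min_total_filter(self):
        cfg = e.SimulationConfig(seed=28, n_genes=60)
        cm, _ = e.simulate_counts(cfg)
        cm.counts.iloc[0] = 0
        res = diffexpr.run_de(cm)
        assert cm.counts.index[0] not in res.index

    def test_invalid_test_name(self):
        cfg = e.SimulationConfig(seed=29, n_genes=20)
        cm, _ = e.simulate_counts(cfg)
        with pytest.raises(ValueError):
            diffexpr.run_de(cm, test="bogus")

    def test_summary_fields(self):
        cfg = e.SimulationConfig(seed=30, n_genes=60)
        cm, _ = e.simulate_counts(cfg)
        res = diffexpr.run_de(cm)
        s = e.de_summary(res)
        assert s["n_analyzed"] == len(res)
        assert s["n_de"] == int((res["q"] < 0.05).sum())
        assert s["n_up"] + s["n_down"] == s["n_de"]
        assert s["pct_de"] == pytest.approx(100 * s["n_de"] / s["n_analyzed"],
                                            abs=0.05)
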