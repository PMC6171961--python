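import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from gwaselect.gwas_core import (additive_scan, conditional_scan,
                                 genomic_control_lambda, pca_covariates,
                                 variance_explained)
from gwaselect.synthetic_data import (SimulationConfig, TraitArchitecture,
                                      simulate_phenotypes,
                                      simulate_populations)


def _variants(n):
    return pd.DataFrame({
        "id": [f"v{j:05d}" for j in range(n)],
        "chrom": "1",
        "pos": np.arange(1, n + 1) * 1000,
        "ref": "A", "alt": "G",
    })


@pytest.fixture
def null_data(rng):
    n, m = 500, 200
    dosages = rng.binomial(2, 0.3, size=(n, m)).astype(float)
    phenotype = rng.normal(size=n)
    covs = pd.DataFrame({"sex": rng.integers(0, 2, n),
                         "age": rng.uniform(30, 70, n)})
    return phenotype, dosages, _variants(m), covs


class TestAdditiveScan:
    def test_matches_statsmodels_ols(self, null_data):
        phenotype, dosages, variants, covs = null_data
        scan = additive_scan(phenotype, dosages, variants, covs)
        j = 17
        x = sm.add_constant(np.column_stack([dosages[:, j], covs.to_numpy()]))
        fit = sm.OLS(phenotype, x).fit()
        rec = scan.records.set_index("ID").loc[variants["id"][j]]
        assert rec["BETA"] == pytest.approx(fit.params[1], rel=1e-10)
        assert rec["SE"] == pytest.approx(fit.bse[1], rel=1e-10)
        assert rec["P"] == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_null_type_one_error(self, rng):
        n, m = 500, 2000
        dosages = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        phenotype = rng.normal(size=n)
        scan = additive_scan(phenotype, dosages, _variants(m))
        frac = (scan.records["P"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07
        assert 0.9 <= scan.lambda_gc <= 1.1

    def test_beta_recovery_on_latent_trait(self):
        cfg = SimulationConfig(n_diploid={"A": 2000}, n_sites=50,
                               sequence_length=50_000, generations=30, seed=9)
        panel = simulate_populations(cfg)[0]["A"]
        arch = TraitArchitecture(causal=[("v00025", 0.5)], noise_sd=1.0)
        _, truth = simulate_phenotypes(panel, arch, seed=10)
        scan = additive_scan(truth.individuals["latent"].to_numpy(),
                             panel.dosages(), panel.variants)
        rec = scan.records.set_index("ID").loc["v00025"]
        assert abs(rec["BETA"] - 0.5) < 2 * rec["SE"]

    def test_monomorphic_column_flagged(self, null_data):
        phenotype, dosages, variants, covs = null_data
        dosages[:, 5] = 2.0
        scan = additive_scan(phenotype, dosages, variants, covs)
        rec = scan.records.set_index("ID").loc[variants["id"][5]]
        assert rec["flag"] == "monomorphic"
        assert np.isnan(rec["P"])

    def test_missing_phenotype_is_error(self, null_data):
        phenotype, dosages, variants, covs = null_data
        phenotype[3] = np.nan
        with pytest.raises(ValueError, match="missing"):
            additive_scan(phenotype, dosages, variants, covs)

    def test_rank_deficient_covariates_error(self, null_data):
        phenotype, dosages, variants, covs = null_data
        covs["sex2"] = covs["sex"]
        with pytest.raises(ValueError, match="rank"):
            additive_scan(phenotype, dosages, variants, covs)

    def test_phenotype_scaling_property(self, null_data):
        phenotype, dosages, variants, covs = null_data
        a = additive_scan(phenotype, dosages, variants, covs).records
        b = additive_scan(3.5 * phenotype, dosages, variants, covs).records
        np.testing.assert_allclose(b["BETA"], 3.5 * a["BETA"])
        np.testing.assert_allclose(b["SE"], 3.5 * a["SE"])
        np.testing.assert_allclose(b["P"], a["P"], rtol=1e-10)

    def test_allele_recoding_flips_beta(self, null_data):
        phenotype, dosages, variants, covs = null_data
        a = additive_scan(phenotype, dosages, variants, covs).records
        b = additive_scan(phenotype, 2.0 - dosages, variants, covs).records
        np.testing.assert_allclose(b["BETA"], -a["BETA"], rtol=1e-10)
        np.testing.assert_allclose(np.abs(b["Z"]), np.abs(a["Z"]), rtol=1e-10)
        np.testing.assert_allclose(b["P"], a["P"], rtol=1e-10)

    def test_records_sorted_by_position(self, rng):
        variants = _variants(5).iloc[::-1].reset_index(drop=True)
        dosages = rng.binomial(2, 0.4, size=(100, 5)).astype(float)
        scan = additive_scan(rng.normal(size=100), dosages, variants)
        assert list(scan.records["POS"]) == sorted(scan.records["POS"])


class TestConditionalScan:
    @pytest.fixture
    def causal_panel(self):
        cfg = SimulationConfig(n_diploid={"A": 1500}, n_sites=40,
                               sequence_length=40_000,
                               recombination_rate=1e-8,  # tight LD block
                               generations=80, seed=21,
                               initial_frequency_range=(0.2, 0.8))
        panel = simulate_populations(cfg)[0]["A"]
        arch = TraitArchitecture(causal=[("v00020", 0.5)], noise_sd=1.0)
        _, truth = simulate_phenotypes(panel, arch, seed=22)
        return panel, truth.individuals["latent"].to_numpy()

    def test_conditioning_on_causal_removes_signal(self, causal_panel):
        panel, y = causal_panel
        naive = additive_scan(y, panel.dosages(), panel.variants)
        assert naive.records["P"].min() < 5e-8  # signal is there
        cond = conditional_scan(y, panel.dosages(), panel.variants, ["v00020"])
        assert "v00020" not in set(cond.records["ID"])
        assert cond.records["P"].dropna().min() > 5e-8

    def test_conditioning_on_uncorrelated_variant(self, causal_panel, rng):
        panel, y = causal_panel
        dosages = np.column_stack([panel.dosages(),
                                   rng.binomial(2, 0.5, len(y))]).astype(float)
        variants = pd.concat([panel.variants, pd.DataFrame([{
            "id": "indep", "chrom": "1", "pos": 999_999,
            "ref": "A", "alt": "G"}])], ignore_index=True)
        naive = additive_scan(y, dosages, variants)
        cond = conditional_scan(y, dosages, variants, ["indep"])
        p0 = naive.records.set_index("ID").loc["v00020", "P"]
        p1 = cond.records.set_index("ID").loc["v00020", "P"]
        assert abs(np.log10(p0) - np.log10(p1)) < 0.5

    def test_empty_condition_equals_additive(self, null_data):
        phenotype, dosages, variants, covs = null_data
        a = additive_scan(phenotype, dosages, variants, covs).records
        b = conditional_scan(phenotype, dosages, variants, [], covs).records
        pd.testing.assert_frame_equal(a, b)

    def test_conditioning_on_monomorphic_is_error(self, null_data):
        phenotype, dosages, variants, covs = null_data
        dosages[:, 0] = 1.0
        with pytest.raises(ValueError, match="monomorphic"):
            conditional_scan(phenotype, dosages, variants,
                             [variants["id"][0]], covs)


class TestGenomicControl:
    def test_unit_lambda_at_null_median(self):
        assert genomic_control_lambda(chi2=np.full(11, 0.45494)) == pytest.approx(
            1.0, abs=1e-4)

    def test_doubled_median(self):
        assert genomic_control_lambda(chi2=np.full(11, 0.90988)) == pytest.approx(
            2.0, abs=1e-4)

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            genomic_control_lambda(p_values=np.array([]))


class TestPca:
    def test_two_populations_separate_on_pc1(self):
        cfg = SimulationConfig(n_diploid={"A": 150, "B": 150}, n_sites=300,
                               sequence_length=300_000, generations=100,
                               split_generation=0, seed=31)
        panels, _ = simulate_populations(cfg)
        dosages = np.vstack([panels["A"].dosages(), panels["B"].dosages()])
        pcs = pca_covariates(dosages, k=2)
        labels = np.r_[np.zeros(150), np.ones(150)]
        r = np.corrcoef(pcs[:, 0], labels)[0, 1]
        assert abs(r) > 0.9

    def test_panmictic_population_has_no_dominant_pc(self, rng):
        dosages = rng.binomial(2, 0.4, size=(300, 400)).astype(float)
        x = (dosages - dosages.mean(0)) / dosages.std(0)
        s = np.linalg.svd(x, compute_uv=False)
        share = s ** 2 / np.sum(s ** 2)
        assert share[0] < 2 * share[1]

    def test_k_zero_gives_empty_block(self, rng):
        dosages = rng.binomial(2, 0.4, size=(50, 30)).astype(float)
        assert pca_covariates(dosages, k=0).shape == (50, 0)

    def test_k_beyond_rank_is_error(self, rng):
        dosages = rng.binomial(2, 0.4, size=(5, 30)).astype(float)
        with pytest.raises(ValueError, match="rank"):
            pca_covariates(dosages, k=10)


class TestVarianceExplained:
    def test_direct_formula(self):
        assert variance_explained(0.5, 0.1, 1.0) == pytest.approx(0.005)

    def test_zero_beta(self):
        assert variance_explained(0.5, 0.0, 1.0) == 0.0

    def test_vanishes_in_rare_allele_limit(self):
        assert variance_explained(1e-9, 0.1, 1.0) == pytest.approx(0.0, abs=1e-8)

    def test_eaf_bounds(self):
        with pytest.raises(ValueError):
            variance_explained(0.0, 0.1, 1.0)

    def test_sigma_positive(self):
        with pytest.raises(ValueError):
            variance_explained(0.5, 0.1, 0.0)
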