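"""Mixed-model scan, RCO phenotype, thresholds, meta- and conditional scans."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, mannwhitneyu, norm

from xoinfer.assoc import (
    bonferroni_threshold,
    compute_rco,
    conditional_scan,
    gwas_scan,
    meta_scan,
    phenotypes_from_estimates,
    vanraden_grm,
)
from xoinfer.core import (
    CrossoverRecord,
    EstimateRecord,
    GenotypeTable,
    HSParameters,
    Meiosis,
)
from xoinfer.simulate import simulate_crossover_positions, uniform_marker_map


def _genotypes(n, k, seed, freqs=None):
    rng = np.random.default_rng(seed)
    if freqs is None:
        freqs = rng.uniform(0.1, 0.5, size=k)
    dos = rng.binomial(2, freqs[None, :], size=(n, k)).astype(np.int8)
    return GenotypeTable(
        [f"s{i}" for i in range(n)],
        [f"snp{j}" for j in range(k)],
        dos,
        ["1"] * k,
        [1000 * (j + 1) for j in range(k)],
    )


class TestBonferroni:
    def test_headline_snp_count(self):
        # 60,577 SNPs at alpha 0.05 -> 8.3e-7 at two significant figures
        thr = bonferroni_threshold(60_577)
        assert f"{thr:.1e}" == "8.3e-07"

    def test_trivial_and_derived_counts(self):
        assert bonferroni_threshold(1) == 0.05
        assert bonferroni_threshold(58_418) == pytest.approx(8.559e-7, rel=1e-3)

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


class TestRCO:
    def _meiosis(self, mids_cm, chrom="1", parent="p1", mid="m1"):
        recs = [
            CrossoverRecord(mid, chrom, f"l{i}", 10 + 20 * i, f"r{i}", 11 + 20 * i, cm)
            for i, cm in enumerate(mids_cm)
        ]
        return Meiosis(mid, parent, "o", "male", None, {chrom: recs})

    def test_double_crossover_ratio(self):
        maps = {"1": uniform_marker_map("1", 1.0, 11)}  # 100 cM
        rco = compute_rco([self._meiosis([30.0, 50.0])], maps)
        assert rco["p1"] == pytest.approx(0.2)

    def test_full_length_distance_is_one(self):
        maps = {"1": uniform_marker_map("1", 1.0, 11)}
        rco = compute_rco([self._meiosis([0.0, 100.0])], maps)
        assert rco["p1"] == pytest.approx(1.0)

    def test_single_crossover_parents_have_no_phenotype(self):
        maps = {"1": uniform_marker_map("1", 1.0, 11)}
        assert "p1" not in compute_rco([self._meiosis([42.0])], maps)

    def test_stronger_interference_larger_rco(self, rng):
        """Gamma-renewal spacing pushes crossovers apart: nu=12 beats nu=1."""
        maps = {"1": uniform_marker_map("1", 1.0, 11)}
        vals = {}
        for label, nu in (("high", 12.0), ("none", 1.0)):
            meioses = []
            _, pos, _ = simulate_crossover_positions(
                HSParameters(nu, 0.0), 1.0, 3000, rng
            )
            for i, x in enumerate(pos):
                meioses.append(self._meiosis(list(100 * x), parent=f"{label}{i}", mid=f"{label}{i}"))
            vals[label] = compute_rco(meioses, maps).to_numpy()
        assert np.median(vals["high"]) > np.median(vals["none"])
        assert mannwhitneyu(vals["high"], vals["none"]).pvalue < 1e-6


class TestScan:
    def _pheno(self, y, ids=None):
        ids = ids or [f"s{i}" for i in range(len(y))]
        return pd.DataFrame({"parent_id": ids, "value": y})

    def test_identity_kinship_equal_weights_matches_ols(self):
        rng = np.random.default_rng(4)
        geno = _genotypes(120, 25, seed=4)
        y = rng.normal(size=120) + 0.4 * geno.dosages[:, 3]
        res = gwas_scan(self._pheno(y), geno, kinship=np.eye(120))
        import statsmodels.api as sm

        for _, row in res.iterrows():
            j = geno.marker_ids.index(row["snp"])
            x = sm.add_constant(geno.dosages[:, j].astype(float))
            ols = sm.OLS(y, x).fit()
            z = ols.params[1] / ols.bse[1]
            p_ref = 2 * norm.sf(abs(z))
            assert row["beta"] == pytest.approx(float(ols.params[1]), rel=1e-6)
            assert row["p"] == pytest.approx(p_ref, rel=1e-6)

    def test_allele_flip_negates_beta_keeps_p(self):
        rng = np.random.default_rng(9)
        geno = _genotypes(100, 10, seed=9)
        y = rng.normal(size=100) + 0.5 * geno.dosages[:, 0]
        res1 = gwas_scan(self._pheno(y), geno)
        flipped = GenotypeTable(
            geno.sample_ids, geno.marker_ids, 2 - geno.dosages,
            list(geno.chromosomes), list(geno.positions_bp),
        )
        res2 = gwas_scan(self._pheno(y), flipped)
        np.testing.assert_allclose(res1["beta"], -res2["beta"], rtol=1e-8)
        np.testing.assert_allclose(res1["p"], res2["p"], rtol=1e-8)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(13)
        geno = _genotypes(80, 12, seed=13)
        y = rng.normal(size=80)
        pheno = self._pheno(y)
        shuffled = pheno.sample(frac=1.0, random_state=1).reset_index(drop=True)
        res1 = gwas_scan(pheno, geno).set_index("snp")
        res2 = gwas_scan(shuffled, geno).set_index("snp")
        np.testing.assert_allclose(res1["p"], res2.loc[res1.index, "p"], rtol=1e-8)

    def test_constant_phenotype_nothing_tested(self):
        geno = _genotypes(50, 5, seed=2)
        res = gwas_scan(self._pheno(np.ones(50)), geno)
        assert len(res) == 0

    def test_monomorphic_and_low_maf_snps_skipped(self):
        rng = np.random.default_rng(3)
        geno = _genotypes(60, 4, seed=3, freqs=np.array([0.3, 0.0, 0.001, 0.4]))
        res = gwas_scan(self._pheno(rng.normal(size=60)), geno)
        assert set(res["snp"]) <= {"snp0", "snp3"}

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(21)
        geno = _genotypes(300, 600, seed=21)
        y = rng.normal(size=300)
        res = gwas_scan(self._pheno(y), geno)
        assert kstest(res["p"], "uniform").statistic < 0.05

    def test_heteroscedastic_weights_accepted(self):
        rng = np.random.default_rng(31)
        geno = _genotypes(90, 8, seed=31)
        pheno = self._pheno(rng.normal(size=90))
        pheno["residual_variance"] = rng.uniform(0.5, 2.0, size=90)
        res = gwas_scan(pheno, geno)
        assert len(res) == 8


class TestConditionalAndMeta:
    def test_zero_covariate_identical_to_unconditional(self):
        rng = np.random.default_rng(8)
        geno = _genotypes(70, 6, seed=8)
        pheno = pd.DataFrame(
            {"parent_id": [f"s{i}" for i in range(70)], "value": rng.normal(size=70)}
        )
        cov = pd.Series(0.0, index=pheno["parent_id"])
        res_c = conditional_scan(pheno, geno, cov)
        res_u = gwas_scan(pheno, geno)
        np.testing.assert_allclose(res_c["p"], res_u["p"], rtol=1e-10)

    def test_empty_second_cohort_equals_single_scan(self):
        rng = np.random.default_rng(12)
        geno = _genotypes(60, 6, seed=12)
        pheno = pd.DataFrame(
            {"parent_id": [f"s{i}" for i in range(60)], "value": rng.normal(size=60)}
        )
        empty = pheno.iloc[:0]
        res_m = meta_scan(pheno, geno, empty, geno)
        res_s = gwas_scan(pheno, geno)
        np.testing.assert_allclose(res_m["p"], res_s["p"], rtol=1e-10)

    def test_disjoint_snp_sets_rejected(self):
        geno_a = _genotypes(30, 4, seed=1)
        geno_b = GenotypeTable(
            [f"t{i}" for i in range(30)],
            [f"other{j}" for j in range(4)],
            geno_a.dosages,
            ["1"] * 4,
            [10 + j for j in range(4)],
        )
        pheno_a = pd.DataFrame({"parent_id": [f"s{i}" for i in range(30)], "value": np.arange(30.0)})
        pheno_b = pd.DataFrame({"parent_id": [f"t{i}" for i in range(30)], "value": np.arange(30.0)})
        with pytest.raises(ValueError):
            meta_scan(pheno_a, geno_a, pheno_b, geno_b)


def test_grm_is_psd_and_centered():
    geno = _genotypes(40, 200, seed=17)
    g = vanraden_grm(geno.dosages)
    assert g.shape == (40, 40)
    eig = np.linalg.eigvalsh(g)
    assert eig.min() > -1e-8
    assert np.mean(np.diag(g)) == pytest.approx(1.0, abs=0.25)


def test_phenotypes_from_estimates_fills_missing_variance():
    recs = [
        EstimateRecord("parent:a", 8.0, 0.05, 1.0, 0.01, -10.0, 30),
        EstimateRecord("parent:b", 9.0, 0.04, None, None, -11.0, 30),
    ]
    df = phenotypes_from_estimates(recs, "nu")
    assert df.loc[df["parent_id"] == "b", "residual_variance"].iloc[0] == 1.0
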