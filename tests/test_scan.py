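"""Per-SNP scans, QC, sequential strategy and evaluation metrics."""
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import survscan as ss
from survscan.exceptions import AlignmentError


def make_null_cohort(seed, n=800, n_snps=50):
    cfg = ss.SimCoxConfig(n_individuals=n, n_snps=n_snps, n_true=0,
                          baseline_scale=1.0, seed=seed)
    return ss.simulate_cox_cohort(cfg)


class TestQc:
    def test_monomorphic_snp_removed_for_maf(self):
        vals = np.column_stack([np.zeros(40), np.random.default_rng(0).integers(0, 3, 40)])
        G = ss.GenotypeMatrix(vals.astype(float), snp_ids=["mono", "ok"])
        kept, log = ss.qc_filter_snps(G, hwe_p_min=0.0)
        assert kept.snp_ids.tolist() == ["ok"]
        assert log.loc[log.snp_id == "mono", "reason"].item() == "maf"

    def test_low_call_rate_removed(self, rng):
        vals = rng.integers(0, 3, size=(100, 2)).astype(float)
        vals[:10, 0] = np.nan  # 10% missing
        G = ss.GenotypeMatrix(vals, snp_ids=["patchy", "ok"])
        kept, log = ss.qc_filter_snps(G, maf_min=0.0, hwe_p_min=0.0,
                                      call_rate_min=0.95)
        assert kept.snp_ids.tolist() == ["ok"]
        assert "call_rate" in log["reason"].iloc[0]

    def test_hwe_exact_matches_full_enumeration(self):
        # independent oracle: exact rational enumeration over heterozygote
        # counts conditional on the minor-allele count
        def exact_p(n_het, n_hom_r, n_hom_c):
            n = n_het + n_hom_r + n_hom_c
            n_rare = 2 * n_hom_r + n_het
            weights = {}
            for het in range(n_rare % 2, n_rare + 1, 2):
                hr = (n_rare - het) // 2
                hc = n - het - hr
                if hc < 0:
                    continue
                w = (Fraction(2) ** het * Fraction(comb(n, het))
                     * Fraction(comb(n - het, hr)))
                weights[het] = w
            total = sum(weights.values())
            obs = weights[n_het]
            return float(sum(w for w in weights.values() if w <= obs) / total)

        for counts in [(20, 30, 50), (2, 1, 97), (50, 25, 25), (0, 10, 90)]:
            got = ss.hwe_exact_test(*counts)
            assert got == pytest.approx(exact_p(*counts), abs=1e-10)

    def test_hwe_filter_on_diploid_matrix(self):
        # 20 hets, 30 rare homs, 50 common homs: large heterozygote deficit
        vals = np.r_[np.ones(20), np.full(30, 2.0), np.zeros(50)]
        G = ss.GenotypeMatrix(vals[:, None], snp_ids=["bad_hwe"], ploidy=2)
        p = ss.hwe_exact_test(20, 30, 50)
        assert p < 0.001
        with pytest.raises(ValueError, match="every SNP"):
            ss.qc_filter_snps(G, maf_min=0.0)

    def test_haploid_matrix_skips_hwe(self):
        rng = np.random.default_rng(1)
        G = ss.GenotypeMatrix(rng.integers(0, 2, (60, 3)).astype(float),
                              ploidy=1)
        kept, log = ss.qc_filter_snps(G, maf_min=0.01)
        assert kept.n_snps == 3 and len(log) == 0


class TestRunScan:
    def test_id_permutation_invariance(self):
        cohort = make_null_cohort(seed=30)
        res = ss.run_scan(cohort.genotypes, cohort.pheno, method="cox")
        perm = np.random.default_rng(0).permutation(len(cohort.pheno))
        res_perm = ss.run_scan(cohort.genotypes, cohort.pheno.subset(perm),
                               method="cox")
        pd.testing.assert_frame_equal(res, res_perm)

    def test_id_mismatch_raises(self):
        cohort = make_null_cohort(seed=31)
        bad = ss.SurvivalPhenotype(cohort.pheno.entry, cohort.pheno.exit,
                                   cohort.pheno.status,
                                   ids=cohort.pheno.ids + 10_000)
        with pytest.raises(AlignmentError):
            ss.run_scan(cohort.genotypes, bad, method="cox")

    def test_causal_snp_has_minimum_p(self):
        cfg = ss.SimCoxConfig(n_individuals=20_000, n_snps=50, n_true=1,
                              coef_low=0.5, coef_high=0.5, baseline_scale=1.0,
                              seed=32)
        cohort = ss.simulate_cox_cohort(cfg)
        for method in ("cox", "logistic"):
            res = ss.scan_cohort(cohort, methods=(method,))
            assert res["p"].idxmin() == 0  # the causal SNP is column 0

    def test_null_p_values_uniform_both_methods(self):
        cfg = ss.SimCoxConfig(n_individuals=1000, n_snps=2000, n_true=0,
                              baseline_scale=1.0, seed=33)
        cohort = ss.simulate_cox_cohort(cfg)
        res = ss.scan_cohort(cohort)
        for method, sub in res.groupby("method"):
            frac = (sub["p"] < 0.05).mean()
            assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / len(sub))

    def test_missing_genotypes_complete_case(self):
        cohort = make_null_cohort(seed=34, n=400, n_snps=3)
        vals = cohort.genotypes.values.copy()
        miss = np.zeros(len(cohort.pheno), dtype=bool)
        miss[::7] = True
        vals[miss, 1] = np.nan
        G = ss.GenotypeMatrix(vals, cohort.genotypes.snp_ids,
                              cohort.genotypes.individual_ids, ploidy=1)
        res = ss.run_scan(G, cohort.pheno, method="cox")
        assert res.loc[1, "n_used"] == (~miss).sum()
        # equals fitting the complete cases directly
        direct = ss.fit_cox(vals[~miss, 1], cohort.pheno.subset(~miss))
        assert res.loc[1, "beta"] == pytest.approx(direct.params[0], rel=1e-9)

    def test_bonferroni_adjustment(self):
        cohort = make_null_cohort(seed=35, n_snps=20)
        res = ss.run_scan(cohort.genotypes, cohort.pheno, method="cox", m=500)
        np.testing.assert_allclose(res["p_bonf"],
                                   np.minimum(1.0, 500 * res["p"]))


class TestSequentialScan:
    def test_stage_assignment_and_filter(self):
        cfg = ss.SimCoxConfig(n_individuals=4000, n_snps=40, n_true=4,
                              coef_low=1.0, coef_high=1.2, baseline_scale=1.0,
                              seed=36)
        cohort = ss.simulate_cox_cohort(cfg)
        cov = ss.scan.cohort_covariates(cohort)
        seq = ss.sequential_scan(cohort.genotypes, cohort.pheno,
                                 covariates_logistic=cov,
                                 status=cohort.status, filter_p=1e-4)
        logi = ss.run_scan(cohort.genotypes, cohort.pheno, cov,
                           method="logistic", status=cohort.status)
        cox = ss.run_scan(cohort.genotypes, cohort.pheno, method="cox")
        passed = logi["p"] <= 1e-4
        assert (seq.loc[passed, "stage"] == "cox").all()
        assert (seq.loc[~passed, "stage"] == "logistic").all()
        assert passed.any() and (~passed).any()
        np.testing.assert_allclose(seq.loc[passed, "p"], cox.loc[passed, "p"])
        np.testing.assert_allclose(seq.loc[~passed, "p"], logi.loc[~passed, "p"])
        assert (seq["method"] == "sequential").all()

    def test_significant_set_matches_cox_when_filter_is_loose(self):
        cfg = ss.SimCoxConfig(n_individuals=20_000, n_snps=30, n_true=5,
                              baseline_scale=1.0, seed=37)
        cohort = ss.simulate_cox_cohort(cfg)
        cov = ss.scan.cohort_covariates(cohort)
        m = 800_000
        seq = ss.sequential_scan(cohort.genotypes, cohort.pheno,
                                 covariates_logistic=cov, status=cohort.status,
                                 filter_p=1e-4, m=m)
        cox = ss.run_scan(cohort.genotypes, cohort.pheno, method="cox", m=m)
        logi = ss.run_scan(cohort.genotypes, cohort.pheno, cov,
                           method="logistic", status=cohort.status, m=m)
        gw = 5e-8
        cox_sig = set(cox.loc[cox["p"] <= gw, "snp_id"])
        premise = set(logi.loc[logi["p"] <= 1e-4, "snp_id"]) >= cox_sig
        assert premise  # loose filter catches all genome-wide-significant SNPs
        seq_sig = set(seq.loc[seq["p"] <= gw, "snp_id"])
        assert seq_sig == cox_sig


class TestEvaluatePower:
    def _result(self, p_bonf, method="cox"):
        m = len(p_bonf)
        return pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(m)],
            "method": method, "p": np.asarray(p_bonf) / 10,
            "p_bonf": p_bonf, "converged": True,
        })

    def test_hand_counted_tpr(self):
        res = self._result([0.005, 0.03, 0.2])
        truth = np.array([True, True, True])
        report = ss.evaluate_power([res], [truth], cutoffs=(0.01, 0.05, 0.1))
        got = report.table.set_index("cutoff")["tpr"]
        assert got[0.01] == pytest.approx(1 / 3)
        assert got[0.05] == pytest.approx(2 / 3)
        assert got[0.1] == pytest.approx(2 / 3)

    def test_perfect_and_empty_detection(self):
        perfect = self._result([0.0, 0.0])
        report = ss.evaluate_power([perfect], [np.array([True, True])])
        assert (report.table["tpr"] == 1.0).all()
        none = self._result([1.0, 1.0])
        report = ss.evaluate_power([none], [np.array([True, False])])
        assert (report.table["tpr"] == 0.0).all()
        assert (report.table["fpr"] == 0.0).all()

    def test_invariant_to_snp_and_replicate_order(self):
        rng = np.random.default_rng(2)
        reps = []
        truths = []
        for _ in range(3):
            p = rng.uniform(size=8)
            reps.append(self._result(p))
            truths.append(rng.uniform(size=8) < 0.5)
        a = ss.evaluate_power(reps, truths)
        # shuffle SNP rows within replicates and reverse replicate order
        shuffled = [r.sample(frac=1, random_state=1).reset_index(drop=True)
                    for r in reps]
        truth_series = [pd.Series(t, index=r["snp_id"])
                        for t, r in zip(truths, reps)]
        b = ss.evaluate_power(shuffled[::-1], truth_series[::-1])
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_non_converged_snps_excluded(self):
        res = self._result([0.001, 0.001])
        res.loc[1, "converged"] = False
        report = ss.evaluate_power([res], [np.array([True, True])])
        assert (report.table["tpr"] == 1.0).all()  # denominator excludes row 1

    def test_bad_cutoff_rejected(self):
        res = self._result([0.5])
        with pytest.raises(ValueError):
            ss.evaluate_power([res], [np.array([True])], cutoffs=(0, 0.5))


class TestGenomicInflation:
    def test_all_half_is_exactly_one(self):
        assert ss.genomic_inflation(np.full(500, 0.5)) == pytest.approx(1.0)

    def test_uniform_p_values_near_one(self, rng):
        p = rng.uniform(size=100_000)
        assert abs(ss.genomic_inflation(p) - 1.0) < 0.02

    def test_scaled_chi_square_recovers_factor(self, rng):
        chi = stats.chi2.rvs(1, size=200_000, random_state=3) * 1.2
        p = stats.chi2.sf(chi, df=1)
        assert ss.genomic_inflation(p) == pytest.approx(1.2, abs=0.02)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            ss.genomic_inflation(np.full(500, 0.0))
        with pytest.raises(ValueError):
            ss.genomic_inflation(np.full(50, 0.5))


class TestCatalogSensitivity:
    def _blocks(self):
        return pd.DataFrame({
            "phenotype": ["a", "a", "a", "b"],
            "block_id": [1, 1, 2, 1],
            "snp_id": ["s0", "s1", "s2", "s3"],
        })

    def test_hand_counted_sensitivity(self):
        res = pd.DataFrame({"snp_id": [f"s{i}" for i in range(4)],
                            "p": [1e-9, 1e-2, 1e-6, 1e-3]})
        out = ss.catalog_sensitivity(res, self._blocks(), [5e-8, 1e-5, 1e-2])
        # best p per block: (a,1)=1e-9, (a,2)=1e-6, (b,1)=1e-3
        np.testing.assert_allclose(out["sensitivity"], [1 / 3, 2 / 3, 1.0])

    def test_perfect_detection(self):
        res = pd.DataFrame({"snp_id": [f"s{i}" for i in range(4)], "p": 0.0})
        out = ss.catalog_sensitivity(res, self._blocks(), [5e-8])
        assert out["sensitivity"].item() == 1.0

    def test_relative_change_between_methods(self):
        res_cox = pd.DataFrame({"snp_id": [f"s{i}" for i in range(4)],
                                "p": [1e-9, 1.0, 1e-9, 1.0]})
        res_log = pd.DataFrame({"snp_id": [f"s{i}" for i in range(4)],
                                "p": [1e-9, 1.0, 1.0, 1.0]})
        out = ss.catalog_sensitivity(res_cox, self._blocks(), [5e-8],
                                     other=res_log)
        assert out["sensitivity"].item() == pytest.approx(2 / 3)
        assert out["sensitivity_other"].item() == pytest.approx(1 / 3)
        assert out["relative_change"].item() == pytest.approx(1.0)

    def test_absent_snp_and_empty_map_rejected(self):
        res = pd.DataFrame({"snp_id": ["s0"], "p": [0.5]})
        with pytest.raises(ValueError, match="absent"):
            ss.catalog_sensitivity(res, self._blocks(), [0.05])
        with pytest.raises(ValueError, match="empty"):
            ss.catalog_sensitivity(res, self._blocks().iloc[:0], [0.05])
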