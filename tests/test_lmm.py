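"""Mixed-model association: GRM, spectral fit, Wald tests, scan behavior."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from ladagrs.containers import CohortLabels, GenotypeMatrix, ValidationError
from ladagrs.lmm import (
    GRM,
    DegeneratePredictorError,
    MixedModelAssociation,
    approx_or,
    association_scan,
    bonferroni_threshold,
    compute_grm,
    eigendecompose,
    fit_lmm_snp,
    reml_lambda,
)
from ladagrs.simulate import (
    SimulatorConfig,
    preset_manifest,
    sample_genotypes,
    simulate_cohort,
)


def _toy_matrix(rng, n=50, m=30):
    freqs = rng.uniform(0.2, 0.8, m)
    return sample_genotypes(freqs, n, rng)


class TestGRM:
    def test_duplicated_individual_shares_grm_entries(self, rng):
        G = _toy_matrix(rng)
        d = G.dosages.copy()
        d[1] = d[0]
        G2 = GenotypeMatrix(G.individual_ids, G.snp_ids, d)
        K = compute_grm(G2).matrix
        assert K[0, 1] == pytest.approx(K[0, 0], abs=1e-12)
        assert K[1, 1] == pytest.approx(K[0, 0], abs=1e-12)

    def test_mean_diagonal_near_one_for_unrelated_cohort(self, rng):
        G = _toy_matrix(rng, n=500, m=2000)
        K = compute_grm(G).matrix
        assert abs(np.diag(K).mean() - 1.0) < 0.05

    def test_sib_pairs_average_half_relatedness(self):
        cfg = SimulatorConfig(
            group_sizes={"CONTROL": 200},
            n_background_snps=1500,
            related_pair_fraction=0.5,
            seed=31,
        )
        G, labels, _ = simulate_cohort(cfg)
        bg = [s for s in G.snp_ids if s.startswith("bg")]
        K = compute_grm(G.subset_snps(bg)).matrix
        # recover the sib pairs as the strongly related entries
        iu = np.triu_indices_from(K, k=1)
        vals = K[iu]
        sibs = vals[vals > 0.25]
        assert len(sibs) >= 30
        assert abs(sibs.mean() - 0.5) < 0.1

    def test_monomorphic_only_rejected(self):
        G = GenotypeMatrix(
            np.array(["a", "b"], dtype=object),
            np.array(["s1"], dtype=object),
            np.array([[2.0], [2.0]]),
        )
        with pytest.raises(ValidationError):
            compute_grm(G)


class TestEigendecompose:
    def test_identity_grm_has_unit_spectrum(self):
        ids = np.array([f"i{k}" for k in range(5)], dtype=object)
        eig = eigendecompose(GRM(np.eye(5), ids))
        assert np.allclose(eig.eigenvalues, 1.0)

    def test_reconstruction_within_tolerance(self, rng):
        A = rng.normal(size=(40, 60))
        K = A @ A.T / 60
        ids = np.array([f"i{k}" for k in range(40)], dtype=object)
        eig = eigendecompose(GRM(K, ids))
        eig.validate(K)  # reconstruction and orthonormality within 1e-8

    def test_rank_one_kernel_has_single_nonzero_eigenvalue(self, rng):
        z = rng.normal(size=25)
        K = np.outer(z, z)
        ids = np.array([f"i{k}" for k in range(25)], dtype=object)
        eig = eigendecompose(GRM(K, ids))
        assert (eig.eigenvalues > 1e-8).sum() == 1

    def test_indefinite_kernel_rejected(self):
        K = np.diag([1.0, -0.5])
        ids = np.array(["a", "b"], dtype=object)
        with pytest.raises(ValidationError):
            eigendecompose(GRM(K, ids))


class TestFitLmmSnp:
    def _ols_reference(self, y, x):
        res = sm.OLS(y, sm.add_constant(x)).fit()
        beta, se = res.params[1], res.bse[1]
        p = stats.chi2.sf((beta / se) ** 2, df=1)
        return beta, se, res.params[0], p

    def test_identity_grm_collapses_to_ols(self, rng):
        n = 200
        ids = np.array([f"i{k}" for k in range(n)], dtype=object)
        eig = eigendecompose(GRM(np.eye(n), ids))
        for _ in range(5):
            x = rng.binomial(2, 0.4, n).astype(float)
            y = (rng.random(n) < 0.4 + 0.05 * x).astype(float)
            if np.unique(y).size < 2:
                continue
            rec = fit_lmm_snp(y, x, eig)
            beta, se, mu, p = self._ols_reference(y, x)
            assert rec.beta == pytest.approx(beta, abs=1e-6)
            assert rec.se == pytest.approx(se, abs=1e-6)
            assert rec.mu == pytest.approx(mu, abs=1e-6)
            assert rec.p == pytest.approx(p, abs=1e-6)

    def test_no_relatedness_argument_equals_identity_grm(self, rng):
        n = 120
        x = rng.binomial(2, 0.3, n).astype(float)
        y = (rng.random(n) < 0.5).astype(float)
        ids = np.array([f"i{k}" for k in range(n)], dtype=object)
        eig = eigendecompose(GRM(np.eye(n), ids))
        a = fit_lmm_snp(y, x, None)
        b = fit_lmm_snp(y, x, eig)
        assert a.beta == pytest.approx(b.beta, abs=1e-9)
        assert a.p == pytest.approx(b.p, abs=1e-9)

    def test_wald_p_invariant_under_allele_flip(self, rng):
        n = 150
        x = rng.binomial(2, 0.3, n).astype(float)
        y = (rng.random(n) < 0.3 + 0.1 * x).astype(float)
        a = fit_lmm_snp(y, x, None)
        b = fit_lmm_snp(y, 2 - x, None)
        assert b.beta == pytest.approx(-a.beta, abs=1e-10)
        assert b.wald_chi2 == pytest.approx(a.wald_chi2, rel=1e-10)
        assert b.p == pytest.approx(a.p, rel=1e-10)

    def test_wald_chi2_matches_beta_over_se(self, rng):
        x = rng.binomial(2, 0.5, 100).astype(float)
        y = (rng.random(100) < 0.5).astype(float)
        rec = fit_lmm_snp(y, x, None)
        assert rec.wald_chi2 == pytest.approx((rec.beta / rec.se) ** 2, rel=1e-12)
        # chi2(1) upper tail at z = 1.95996 is 0.05
        assert stats.chi2.sf(1.95996**2, 1) == pytest.approx(0.05, abs=1e-4)

    def test_reml_recovers_heritable_structure(self, rng):
        # phenotype dominated by the random effect -> large lambda
        n = 200
        A = rng.normal(size=(n, 300))
        K = A @ A.T / 300
        ids = np.array([f"i{k}" for k in range(n)], dtype=object)
        eig = eigendecompose(GRM(K, ids))
        L = np.linalg.cholesky(K + 1e-6 * np.eye(n))
        g = L @ rng.normal(size=n)
        y = (g + 0.1 * rng.normal(size=n) > 0).astype(float)
        lam_structured = reml_lambda(y, eig)
        y_perm = rng.permutation(y)
        lam_null = reml_lambda(y_perm, eig)
        assert lam_structured > lam_null

    def test_degenerate_inputs_rejected(self):
        y = np.array([0.0, 1.0, 0.0, 1.0])
        with pytest.raises(DegeneratePredictorError):
            fit_lmm_snp(y, np.ones(4), None)
        with pytest.raises(ValidationError):
            fit_lmm_snp(np.zeros(4), np.array([0.0, 1, 2, 1]), None)


class TestApproxOR:
    def test_exponent_mode_closed_forms(self):
        assert approx_or(0.0, 0.4) == pytest.approx(1.0)
        assert approx_or(0.25, 0.5) == pytest.approx(math.e, rel=1e-12)

    def test_literal_mode_matches_published_formula(self):
        assert approx_or(1.0, 0.5, mode="LITERAL") == pytest.approx(
            1 / math.exp(0.25), rel=1e-12
        )

    def test_exponent_mode_rejects_intercept_outside_unit_interval(self):
        with pytest.raises(ValidationError):
            approx_or(0.1, 1.5)


class TestAssociationScan:
    def _two_group_cohort(self, seed, freq_a=0.5, freq_b=0.5, n=300, m=67):
        rng = np.random.default_rng(seed)
        ga = rng.binomial(2, freq_a, size=(n, m)).astype(float)
        gb = rng.binomial(2, freq_b, size=(n, m)).astype(float)
        from ladagrs.containers import LocusRecord, LocusManifest

        snps = [f"rs{j}" for j in range(m)]
        manifest = LocusManifest(
            [LocusRecord(s, "1", j + 1, "A", "G", "T1D", 1.1) for j, s in enumerate(snps)]
        )
        ids = np.array([f"i{k}" for k in range(2 * n)], dtype=object)
        G = GenotypeMatrix(ids, np.array(snps, dtype=object), np.vstack([ga, gb]))
        labels = CohortLabels.from_arrays(
            ids.tolist(), ["LADA"] * n + ["CONTROL"] * n
        )
        return G, labels, manifest

    def test_bonferroni_thresholds_for_both_panels(self):
        assert bonferroni_threshold(0.05, 67) == pytest.approx(7.46e-4, abs=5e-7)
        assert bonferroni_threshold(0.05, 71) == pytest.approx(7.04e-4, abs=5e-7)

    def test_null_panel_yields_no_bonferroni_hits(self):
        G, labels, manifest = self._two_group_cohort(seed=41)
        records = association_scan(G, labels, manifest, "LADA", "CONTROL")
        assert sum(r.significant for r in records) == 0
        assert len(records) == 67

    def test_records_sorted_by_p_and_carry_group_frequencies(self):
        G, labels, manifest = self._two_group_cohort(seed=43, freq_a=0.7, freq_b=0.5)
        records = association_scan(G, labels, manifest, "LADA", "CONTROL")
        ps = [r.p for r in records]
        assert ps == sorted(ps)
        top = records[0]
        assert abs(top.freq_a - 0.7) < 0.06
        assert abs(top.freq_b - 0.5) < 0.06

    def test_constant_snp_reported_with_reason_not_dropped(self):
        G, labels, manifest = self._two_group_cohort(seed=47, m=5)
        G.dosages[:, 2] = 2.0
        records = association_scan(G, labels, manifest, "LADA", "CONTROL")
        assert len(records) == 5
        skipped = [r for r in records if r.reason is not None]
        assert len(skipped) == 1 and skipped[0].reason == "constant_dosage"

    def test_empty_group_rejected(self):
        G, labels, manifest = self._two_group_cohort(seed=49, m=3)
        with pytest.raises(ValidationError):
            association_scan(G, labels, manifest, "LADA", "T1D")

    def test_case_case_contrast_detects_frequency_difference(self):
        cfg = SimulatorConfig(
            group_sizes={"LADA": 400, "T1D": 400},
            n_background_snps=0,
            seed=53,
        )
        G, labels, manifest = simulate_cohort(cfg)
        records = association_scan(
            G, labels, manifest, "LADA", "T1D", panel="T1D", n_tests=67
        )
        by_id = {r.snp_id: r for r in records}
        # MHC frequencies 0.686 vs 0.818 differ strongly at this size
        assert by_id["rs9272346"].p < by_id["rs17696736"].p

    def test_antibody_subset_restricts_cases(self):
        cfg = SimulatorConfig(
            group_sizes={"LADA": 300, "CONTROL": 300},
            n_background_snps=0,
            seed=59,
        )
        G, labels, manifest = simulate_cohort(cfg)
        records = association_scan(
            G, labels, manifest, "LADA", "CONTROL", subset_a="GADA_IA2A"
        )
        n_ri = labels.subset_mask("GADA_IA2A", G.individual_ids).sum()
        assert records[0].n_used == n_ri + 300


class TestEstimator:
    def test_sklearn_contract(self, rng):
        from sklearn.base import clone

        est = MixedModelAssociation()
        est2 = clone(est)
        X = rng.binomial(2, 0.4, size=(100, 5)).astype(float)
        y = (rng.random(100) < 0.5).astype(float)
        est2.fit(X, y)
        assert len(est2.results_) == 5
        assert est2.n_features_in_ == 5
        assert est2.pvalues_().shape == (5,)
        assert est.get_params()["per_snp_reml"] is False
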