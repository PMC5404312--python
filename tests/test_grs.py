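"""Genetic risk scores: panel selection, HLA diplotypes, scoring oracle."""

import math

import numpy as np
import pytest

from ladagrs.containers import (
    GenotypeMatrix,
    LocusManifest,
    LocusRecord,
    ValidationError,
)
from ladagrs.grs import (
    GeneticRiskScorer,
    GRSWeightSet,
    compute_grs,
    infer_hla_diplotype,
    select_grs_snps,
)
from ladagrs.simulate import (
    assign_status_logistic,
    preset_manifest,
    sample_genotypes,
)


def _matrix_from(dosages, snp_ids):
    dosages = np.asarray(dosages, dtype=float)
    ids = np.array([f"i{k}" for k in range(dosages.shape[0])], dtype=object)
    return GenotypeMatrix(ids, np.array(snp_ids, dtype=object), dosages)


class TestSelectGrsSnps:
    def test_missing_or_excluded_from_panel(self):
        manifest = preset_manifest()
        t1d = select_grs_snps(manifest, "T1D")
        assert "rs7111341" not in t1d.snp_ids  # no published OR
        assert "rs11171710" not in t1d.snp_ids

    def test_both_panel_snp_excluded_everywhere(self):
        manifest = preset_manifest()
        for score_type in ("T1D", "T2D", "COMBINED", "T1D_NO_HLA", "HLA_ONLY"):
            assert "rs7202877" not in select_grs_snps(manifest, score_type).snp_ids

    def test_hla_partitions(self):
        manifest = preset_manifest()
        hla = select_grs_snps(manifest, "HLA_ONLY")
        no_hla = select_grs_snps(manifest, "T1D_NO_HLA")
        assert set(hla.snp_ids) == {"rs9272346", "rs2187668", "rs7454108"}
        assert set(no_hla.snp_ids).isdisjoint(hla.snp_ids)
        t1d = select_grs_snps(manifest, "T1D")
        assert set(t1d.snp_ids) == set(hla.snp_ids) | set(no_hla.snp_ids)

    def test_combined_is_union_of_panels(self):
        manifest = preset_manifest()
        combined = set(select_grs_snps(manifest, "COMBINED").snp_ids)
        t1d = set(select_grs_snps(manifest, "T1D").snp_ids)
        t2d = set(select_grs_snps(manifest, "T2D").snp_ids)
        assert combined == t1d | t2d

    def test_empty_selection_names_score_type(self):
        manifest = LocusManifest(
            [LocusRecord("rs1", "1", 1, "A", "G", "T2D", 1.2)]
        )
        with pytest.raises(ValidationError, match="T1D"):
            select_grs_snps(manifest, "T1D")


class TestHlaDiplotype:
    @pytest.mark.parametrize(
        "d3,d4,expected",
        [
            (2, 0, "DR3/DR3"),
            (1, 1, "DR3/DR4"),
            (0, 2, "DR4/DR4"),
            (1, 0, "DR3/X"),
            (0, 1, "DR4/X"),
            (0, 0, "X/X"),
            (2, 1, "INCONSISTENT"),
            (2, 2, "INCONSISTENT"),
        ],
    )
    def test_category_from_tag_counts(self, d3, d4, expected):
        assert infer_hla_diplotype(d3, d4) == expected

    def test_missing_dosage_is_unresolvable(self):
        assert infer_hla_diplotype(float("nan"), 1) is None


class TestComputeGrs:
    def test_unit_odds_ratios_give_zero_scores(self):
        G = _matrix_from([[0, 1], [2, 2]], ["rs1", "rs2"])
        w = GRSWeightSet("T1D", {"rs1": 0.0, "rs2": 0.0})
        vec = compute_grs(G, w)
        assert (vec.scores == 0).all()

    def test_single_snp_closed_form(self):
        G = _matrix_from([[2]], ["rs1"])
        w = GRSWeightSet("T1D", {"rs1": math.log(2)})
        assert compute_grs(G, w).scores.iloc[0] == pytest.approx(
            2 * math.log(2), rel=1e-12
        )

    def test_vectorized_scores_match_bruteforce(self, rng):
        m, n = 20, 40
        dosages = rng.integers(0, 3, size=(n, m)).astype(float)
        snps = [f"rs{j}" for j in range(m)]
        G = _matrix_from(dosages, snps)
        weights = {s: rng.normal() for s in snps}
        vec = compute_grs(G, GRSWeightSet("T1D", weights))
        for i in range(n):
            brute = sum(dosages[i, j] * weights[snps[j]] for j in range(m))
            assert vec.scores.iloc[i] == pytest.approx(brute, abs=1e-12)

    def test_missing_dosage_imputed_at_twice_sample_frequency(self):
        G = _matrix_from([[0], [2], [np.nan]], ["rs1"])
        w = GRSWeightSet("T1D", {"rs1": 1.0})
        vec = compute_grs(G, w)
        assert vec.scores.iloc[2] == pytest.approx(2 * 0.5)  # freq from obs = 0.5

    def test_weight_without_matching_snp_rejected(self):
        G = _matrix_from([[1]], ["rs1"])
        with pytest.raises(ValidationError, match="rs2"):
            compute_grs(G, GRSWeightSet("T1D", {"rs2": 0.5}))

    def test_monotone_in_risk_alleles(self):
        w = GRSWeightSet("T1D", {"rs1": 0.3, "rs2": 0.7})
        lo = compute_grs(_matrix_from([[1, 1]], ["rs1", "rs2"]), w).scores.iloc[0]
        hi = compute_grs(_matrix_from([[1, 2]], ["rs1", "rs2"]), w).scores.iloc[0]
        assert hi > lo

    def test_combined_equals_sum_of_panels(self, rng):
        manifest = preset_manifest()
        snps = select_grs_snps(manifest, "COMBINED").snp_ids
        freqs = rng.uniform(0.2, 0.8, len(snps))
        G = sample_genotypes(freqs, 50, rng)
        G = GenotypeMatrix(G.individual_ids, np.array(snps, dtype=object), G.dosages)
        t1d = GeneticRiskScorer(manifest, "T1D").fit().score_vector(G)
        t2d = GeneticRiskScorer(manifest, "T2D").fit().score_vector(G)
        comb = GeneticRiskScorer(manifest, "COMBINED").fit().score_vector(G)
        assert np.allclose(
            comb.scores.to_numpy(),
            t1d.scores.to_numpy() + t2d.scores.to_numpy(),
            atol=1e-12,
        )

    def test_orientation_flip_shifts_scores_by_constant(self, rng):
        # flipping a locus (alleles swapped, OR inverted, dosages 2-d)
        # changes every score by exactly 2*ln(OR)
        snps = ["rs1", "rs2", "rs3"]
        records = [
            LocusRecord("rs1", "1", 1, "A", "G", "T1D", 1.5),
            LocusRecord("rs2", "1", 2, "C", "T", "T1D", 1.2),
            LocusRecord("rs3", "1", 3, "G", "A", "T1D", 1.1),
        ]
        manifest = LocusManifest(records)
        dosages = rng.integers(0, 3, size=(30, 3)).astype(float)
        G = _matrix_from(dosages, snps)
        base = GeneticRiskScorer(manifest, "T1D").fit().score_vector(G)
        flipped_manifest = LocusManifest([records[0].flipped(), *records[1:]])
        flipped_dosages = dosages.copy()
        flipped_dosages[:, 0] = 2 - flipped_dosages[:, 0]
        G_flip = _matrix_from(flipped_dosages, snps)
        flipped = GeneticRiskScorer(flipped_manifest, "T1D").fit().score_vector(G_flip)
        diff = base.scores.to_numpy() - flipped.scores.to_numpy()
        assert np.allclose(diff, 2 * math.log(1.5), atol=1e-12)

    def test_cases_from_logistic_model_score_higher(self, rng):
        from scipy.stats import mannwhitneyu

        manifest = preset_manifest()
        t1d = select_grs_snps(manifest, "T1D")
        freqs = [0.3] * len(t1d)
        G = sample_genotypes(freqs, 2000, rng)
        G = GenotypeMatrix(
            G.individual_ids, np.array(t1d.snp_ids, dtype=object), G.dosages
        )
        weights = [math.log(manifest[s].published_or) for s in t1d.snp_ids]
        y = assign_status_logistic(G, weights, intercept=-1.0, seed=67)
        vec = GeneticRiskScorer(manifest, "T1D").fit().score_vector(G)
        s = vec.scores.to_numpy()
        p = mannwhitneyu(s[y == 1], s[y == 0], alternative="greater").pvalue
        assert p < 1e-6


class TestDiplotypeWeighting:
    def _cohort(self):
        manifest = preset_manifest()
        snps = select_grs_snps(manifest, "T1D").snp_ids
        n = 6
        dosages = np.ones((n, len(snps)))
        j3 = snps.index("rs2187668")
        j4 = snps.index("rs7454108")
        dosages[:, j3] = [2, 1, 0, 1, 0, 0]
        dosages[:, j4] = [0, 1, 2, 0, 1, 0]
        return manifest, _matrix_from(dosages, snps), j3, j4

    def test_diplotype_weight_replaces_additive_tags(self):
        manifest, G, j3, j4 = self._cohort()
        dip = {c: 1.0 for c in
               ("DR3/DR3", "DR3/DR4", "DR4/DR4", "DR3/X", "DR4/X", "X/X")}
        with_dip = GeneticRiskScorer(
            manifest, "T1D", hla_diplotype_weights=dip
        ).fit().score_vector(G)
        plain = GeneticRiskScorer(manifest, "T1D").fit().score_vector(G)
        w3 = math.log(manifest["rs2187668"].published_or)
        w4 = math.log(manifest["rs7454108"].published_or)
        # individual 5 is X/X: additive tags contribute 0, diplotype adds 1
        assert with_dip.scores.iloc[5] == pytest.approx(plain.scores.iloc[5] + 1.0)
        # individual 0 is DR3/DR3: additive would add 2*w3
        assert with_dip.scores.iloc[0] == pytest.approx(
            plain.scores.iloc[0] - 2 * w3 + 1.0
        )

    def test_inconsistent_category_falls_back_to_additive(self, caplog):
        manifest, G, j3, j4 = self._cohort()
        d = G.dosages.copy()
        snps = G.snp_ids.tolist()
        d[0, snps.index("rs2187668")] = 2
        d[0, snps.index("rs7454108")] = 2
        G2 = GenotypeMatrix(G.individual_ids, G.snp_ids, d)
        dip = {c: 5.0 for c in
               ("DR3/DR3", "DR3/DR4", "DR4/DR4", "DR3/X", "DR4/X", "X/X")}
        with caplog.at_level("WARNING"):
            with_dip = GeneticRiskScorer(
                manifest, "T1D", hla_diplotype_weights=dip
            ).fit().score_vector(G2)
        plain = GeneticRiskScorer(manifest, "T1D").fit().score_vector(G2)
        assert with_dip.scores.iloc[0] == pytest.approx(plain.scores.iloc[0])
        assert "fell back" in caplog.text

    def test_transform_returns_column(self):
        manifest, G, _, _ = self._cohort()
        out = GeneticRiskScorer(manifest, "T1D").fit_transform(G)
        assert out.shape == (G.n_individuals, 1)
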