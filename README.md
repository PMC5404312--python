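# ladagrs

Genetic placement of latent autoimmune diabetes in adults (LADA)
between type 1 (T1D) and type 2 diabetes (T2D): a mixed-model
candidate-SNP association scan, log-odds-weighted genetic risk scores
(GRS), ROC-based discrimination of diagnostic groups, and
population-structure/calibration diagnostics — exercised on a built-in
cohort simulator, so the whole pipeline is testable without
access-controlled genotype data.

Intended users: statistical geneticists and methods developers who want
a compact, fully reproducible implementation of the
case/control-and-case/case candidate-SNP workflow for diabetes
subtypes, or a simulation harness for teaching and benchmarking it.

## The statistics

**Association.** Each SNP's risk-allele dosage `x` is tested against a
binary phenotype `y` (case group = 1) under a linear mixed model

&nbsp;&nbsp;&nbsp;&nbsp;y = μ·1 + xβ + g + e, g ~ N(0, σ²_g K), e ~ N(0, σ²_e I),

with `K` the standardized genetic relationship matrix from background
SNPs. REML estimates λ = σ²_g/σ²_e in the eigenbasis of `K`; the Wald
statistic (β̂/SE)² is referred to χ²(1), and significance uses
Bonferroni cutoffs α/n (0.05/67 = 7.46×10⁻⁴ for the T1D panel,
0.05/71 = 7.04×10⁻⁴ for T2D). Approximate odds ratios come from
OR = exp(β/(μ(1−μ))). Case-vs-case contrasts (e.g. LADA vs T1D) are
the same scan with both groups being case groups.

**Risk scores.** GRS_i = Σ_j dosage_ij · ln(OR_j) over a panel's loci
with published odds ratios; loci implicated in both diseases are
excluded, and HLA DR3/DR4-DQ8 tag SNPs can be scored through inferred
diplotype categories. Discrimination is summarized by the
tie-corrected Mann–Whitney AUC; score distributions across the six
diagnostic groups are compared with Bonferroni-adjusted Wilcoxon
rank-sum tests.

**Diagnostics.** LD pruning, PCA of standardized genotypes, QQ plots
and the genomic inflation factor λ = median(χ²)/0.455.

**Simulator.** Binomial(2, p) dosages at group-specific candidate
frequencies (the built-in panel carries the published MHC/PTPN22/
SH2B3/INS/SMARCE1/HNF1A/TCF7L2/ZBED3 frequencies), Balding–Nichols
subpopulation structure, sib-pair relatedness, batch-wise missingness,
and antibody-defined LADA subsets (GADA-only / GADA+IA2A+). See
`docs/methods.md` for every default and its rationale.

## Worked example

```python
from ladagrs import (SimulatorConfig, simulate_cohort, association_scan,
                     compute_grm, GeneticRiskScorer, roc_auc)

cfg = SimulatorConfig(
    group_sizes={"LADA": 978, "CONTROL": 1057},
    n_background_snps=500,
    fst=0.05, n_subpops=2, subpop_group_bias=0.3,
    related_pair_fraction=0.1, seed=42,
)
G, labels, manifest = simulate_cohort(cfg)

bg = [s for s in G.snp_ids if s.startswith("bg")]
grm = compute_grm(G.subset_snps(bg))
records = association_scan(G, labels, manifest, "LADA", "CONTROL",
                           panel="T1D", n_tests=67, grm=grm)
for r in records[:4]:
    print(f"{r.snp_id:<11} freq_LADA={r.freq_a:.3f} freq_CTRL={r.freq_b:.3f} "
          f"beta={r.beta:+.4f} p={r.p:.2e} OR={r.or_approx:.3f} "
          f"sig={r.significant}")

case = labels.group_mask("LADA", G.individual_ids)
for score_type in ("T1D", "T2D"):
    s = GeneticRiskScorer(manifest, score_type).fit_transform(G)[:, 0]
    print(f"AUC({score_type} GRS, LADA vs control) = "
          f"{roc_auc(s, case.astype(int)).auc:.3f}")
```

Output:

```
rs9272346   freq_LADA=0.694 freq_CTRL=0.570 beta=+0.1217 p=7.03e-16 OR=1.738 sig=True
rs7454108   freq_LADA=0.184 freq_CTRL=0.098 beta=+0.1615 p=1.02e-14 OR=1.929 sig=True
rs2187668   freq_LADA=0.208 freq_CTRL=0.117 beta=+0.1523 p=1.22e-13 OR=1.860 sig=True
rs7111341   freq_LADA=0.788 freq_CTRL=0.731 beta=+0.0735 p=2.53e-05 OR=1.371 sig=True
AUC(T1D GRS, LADA vs control) = 0.677
AUC(T2D GRS, LADA vs control) = 0.533
```

The MHC and HLA tag loci, whose configured LADA/control frequency gaps
are largest, dominate the scan and pass the 7.46×10⁻⁴ threshold; the
T1D-weighted score separates simulated LADA cases from controls much
better than the T2D-weighted score, the qualitative signature of
LADA's autoimmune component.

`GeneticRiskScorer`, `MixedModelAssociation` and `GenotypePCA` follow
scikit-learn's estimator conventions (`fit`/`transform`,
`get_params`, trailing-underscore attributes) and compose with sklearn
tooling.

## Command line

```bash
ladagrs simulate --seed 1 --out cohort/          # genotypes + labels + manifest
ladagrs run-all  --seed 1 --out report/          # the full study in one directory
ladagrs assoc --group-a LADA --group-b T1D --panel T1D --seed 1 --out scan/
```

`run-all` writes association tables for every case subset against
controls and against the T1D/T2D case groups, score files, the AUC
summary grid, pairwise rank-sum matrices, PCA/λ/QQ diagnostics, and a
run log. All tables are TSV; reruns with the same seed are
byte-identical.

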