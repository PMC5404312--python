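# Methods

`ladagrs` re-creates, on simulated data, the analysis used to place
latent autoimmune diabetes in adults (LADA) genetically between type 1
(T1D) and type 2 diabetes (T2D): a candidate-SNP association scan under
a linear mixed model, log-odds-weighted genetic risk scores (GRS), and
ROC/rank-based comparison of score distributions across diagnostic
groups. This note documents the models, the defaults and why they were
chosen, and what the simulator does and does not emulate.

## Mixed-model association

For each candidate SNP the binary phenotype (case group coded 1,
comparison group 0) is regressed on risk-allele dosage under

    y = mu·1 + x·beta + g + e,   g ~ N(0, sg² K),   e ~ N(0, se² I),

where `K` is the standardized genetic relationship matrix (GRM)
computed from background SNPs, `K = (1/m) Σ_j z_j z_jᵀ` with
`z_j = (g_j − 2p̂_j)/sqrt(2p̂_j(1−p̂_j))`. The phenotype stays on the
0/1 scale — no liability-threshold transformation — matching the usual
mixed-model GWAS treatment of case/control traits.

Fitting is spectral: after rotating by the eigenvectors of `K`, the
observations are independent with variances `se²(λ d_i + 1)` for the
variance ratio `λ = sg²/se²`. REML reduces to a one-dimensional search
over `log λ ∈ [−5, 5]` (Brent, tolerance 1e-6), followed by generalized
least squares. The Wald statistic `(β̂/SE)²` is referred to χ²(1).

Two deliberate shortcuts, both standard practice:

* **Null-model variance ratio.** `λ` is estimated once per phenotype at
  the intercept-only model and reused for every SNP (the
  "population parameters previously determined" approximation). Exact
  per-SNP re-estimation is available via `per_snp_reml=True`; for
  candidate panels of ~70 SNPs either is affordable, but the shortcut
  is simpler to reason about and test.
* **Identity kernel when unrelated.** `association_scan(grm=None)`
  skips the eigendecomposition; the model then collapses exactly to
  ordinary least squares (verified to 1e-6 in the tests). This is the
  appropriate path for simulated cohorts generated without structure or
  relatedness.

Missing dosages are mean-imputed within the contrasted sample before
fitting; reported risk-allele frequencies use observed calls only.
Bonferroni significance uses `alpha / n_tests`, which for the 67-SNP
T1D panel and 71-SNP T2D panel gives 7.46e-4 and 7.04e-4.

### Odds-ratio approximation

Effect sizes on the linear 0/1 scale are converted to approximate odds
ratios. The default (`EXPONENT`) is `OR = exp(β/(μ(1−μ)))`, the usual
linear-probability-to-log-odds conversion at baseline prevalence `μ`.
A `LITERAL` mode computes `β / e^{μ(1−μ)}` instead. The literal form
returns 0 at `β = 0` and is dimensionally inconsistent with a
near-null OR of ~1, so it is not the default, but it is retained
because it has circulated in print; neither mode is claimed to
reproduce any particular external implementation.

## Genetic risk scores

A score is `score_i = Σ_j dosage_ij · ln(OR_j)` over the loci of a
panel. Panel rules: loci without a published OR and loci implicated in
both diseases never enter any score; `T1D_NO_HLA` drops all HLA-tagged
loci; `HLA_ONLY` keeps only them. Manifest records whose published OR
is below 1 are re-oriented at load (alleles swapped, OR inverted) so
every weight counts risk-increasing alleles.

The two HLA class II tag SNPs (DR3 tag rs2187668, DR4-DQ8 tag
rs7454108) are weighted additively by default. An optional diplotype
mode infers the category (DR3/DR3, DR3/DR4, DR4/DR4, DR3/X, DR4/X,
X/X) from joint tag counts — a total tag count above 2 is flagged
INCONSISTENT — and substitutes a config-injected category weight for
the additive tag contribution. The diplotype weight table is injected
rather than built in because no published per-category weights are
bundled with the package; unresolvable or inconsistent categories fall
back to additive weighting with a warning.

Missing dosages are imputed as twice the scored sample's risk-allele
frequency (the common scoring-tool default); an omit-and-rescale mode
(`total weight / observed weight`) is available.

## Discrimination and distribution comparison

AUC is computed from midranks (tie-corrected Mann–Whitney), which
equals the trapezoidal area under the tie-collapsed ROC curve and the
exhaustive pairwise win fraction; tests assert both identities to
1e-12. AUC is taken directly on the score rather than on logistic
fitted probabilities: for a single monotone predictor the two are
identical, and the direct route does not depend on fit convergence.
Logistic fits (IRLS, convergence 1e-8, max 100 iterations) are still
provided for coefficient inference; perfect separation is detected and
raised as a distinct error rather than returning diverged estimates.

Score distributions across the six groups (T1D, T2D, LADA, GADA-only
LADA, GADA+IA2A+ LADA, controls) are compared with two-sided Wilcoxon
rank-sum tests — exact enumeration when both groups have ≤ 10
observations and no ties, otherwise the normal approximation with
continuity and tie correction — Bonferroni-adjusted over the number of
pairs actually tested (15 for six groups).

## QC diagnostics

* **LD pruning**: greedy sliding window (window 50, step 5, r² 0.2 —
  community-conventional defaults, since no published parameters exist
  for this analysis), removing the lower-MAF member of each correlated
  pair.
* **PCA**: top-k eigenvectors of the standardized-genotype covariance,
  scaled by sqrt(eigenvalue); signs fixed by making each axis's
  largest-magnitude coordinate positive, so output is deterministic.
* **Genomic inflation**: `λ = median(χ²_obs)/0.4549364…` using the
  exact χ²(1) median rather than the rounded 0.456, so a constant
  p = 0.5 maps to λ = 1 exactly.

## The cohort simulator

The simulator generates the data layout the analysis assumes, not real
genetics:

* **Group sizes** default to 978 LADA / 1057 controls / 2000 T1D /
  1960 T2D, with the LADA group split 669 GADA-only / 309 GADA+IA2A+.
* **Candidate loci** are sampled as independent Binomial(2, p) dosages
  at group-specific risk-allele frequencies. The built-in panel carries
  the loci with published group frequencies (MHC rs9272346 at
  0.686/0.818/0.579 for LADA/T1D/controls, PTPN22, SH2B3, the two INS
  signals, SMARCE1, HNF1A, TCF7L2, ZBED3) plus the HLA tag SNPs and the
  conventionally excluded loci (no-OR and both-disease), so every
  selection rule is exercised. Where a (locus, group) frequency was
  never published — the HLA tag SNPs, the overall-LADA frequency of
  rs7111341 and rs6878122, and cross-disease frequencies — realistic
  European-ancestry values were chosen once and fixed. Published
  per-locus weights for the full 67+71 panels are not publicly printed,
  so the preset manifest uses the reported mixed-model ORs (and, for
  TCF7L2, the well-known ~1.37 T2D effect) as stand-in weights; panel
  membership is entirely manifest-driven, and users can supply their
  own manifest.
* **Antibody subsets**: when a restricted-subset frequency is
  configured, the GADA-only frequency is recovered by mixture inversion
  so the pooled LADA frequency stays at its configured value. An
  optional enrichment mode instead assigns GADA+IA2A+ membership to the
  highest T1D-panel liability, reproducing qualitatively the sharper
  discrimination of the restricted subset.
* **Structure**: background SNPs draw subpopulation frequencies from
  the Balding–Nichols model, Beta(p(1−F)/F, (1−p)(1−F)/F).
  `subpop_group_bias` makes controls favor subpopulation 0, emulating
  case/control cohorts ascertained from different strata — without it,
  group and ancestry are independent and structure cannot confound.
* **Relatedness**: sib pairs drawn from shared parental haplotypes
  (expected GRM entry 0.5) — the simplest structure the mixed model
  must absorb.
* **LD**: candidate loci are independent except for optional correlated
  pairs (e.g. the two INS signals at r² = 0.278), generated by copying
  haplotype alleles with a mixing probability solved from the target
  correlation (exact when the pair's frequencies are equal, very close
  otherwise).
* **Missingness**: applied after sampling, completely at random within
  batch, per-batch rates; no genotype-calling error model.

Not emulated: haplotype-level MHC variation, imputation, array-specific
QC, linkage beyond the configured pairs, and any environmental or
clinical covariates. Passing tests therefore demonstrate the
statistical machinery — calibration, power at configured frequency
gaps, score algebra, discrimination direction — not the real-data
effect sizes, which depend on access-controlled genotypes.

## Numerical choices and degenerate inputs

* GRM: monomorphic SNPs excluded; symmetry enforced to 1e-10;
  eigenvalues below −1e-8 are an error, small negatives are clipped.
* REML: `log λ` bounded in [−5, 5]; a constant dosage vector or a
  single-class phenotype raises a typed error, and scan-level constant
  SNPs are reported with a reason code instead of being dropped.
* Rank tests with all observations identical return p = 1 (the
  tie-corrected variance is zero, so there is no evidence of a shift).
* All simulator randomness flows from one seed through
  `numpy.random.SeedSequence.spawn`, so stages are independently
  reproducible and outputs are byte-identical across reruns.

## Known limitations

* Building the GRM from the same background SNPs that are then tested
  (proximal contamination) deflates the null statistics slightly; the
  inflation factor on structured null simulations typically lands at
  0.90–0.97 rather than exactly 1, consistent with the mild deflation
  such designs show on real data. A leave-out kernel is not
  implemented.
* The linear model of a binary trait approximates; odds ratios are
  approximations from (β, μ), not logistic-model estimates.
* Simulation sizes in the test-suite and acceptance script (e.g. 1000
  null SNPs at n = 1000; 100 replicates for power and direction
  checks) were chosen as the smallest designs whose acceptance bands
  are statistically stable.
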