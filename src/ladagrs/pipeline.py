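"""End-to-end orchestration: simulate (or load), scan, score, classify, QC.

``run_all`` emits, under one report directory:

* ``assoc_<panel>_<subset>_vs_<group>.tsv`` — association tables for each
  case subset against controls and against the T1D/T2D case groups;
* ``scores.tsv`` and ``auc_summary.tsv`` (+ per-cell ``roc_*.tsv``) — the
  score files and the AUC grid over score types x case subsets;
* ``pairwise_T1D.tsv`` / ``pairwise_T2D.tsv`` — rank-sum test matrices
  over the six diagnostic groups;
* ``pca.tsv``, ``inflation.tsv``, ``qq.tsv`` — structure/calibration QC;
* ``run_log.txt`` — versions, seed and config echo.

All randomness flows from ``RunConfig.seed`` through a single
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .classify import pairwise_rank_tests, roc_auc
from .containers import CohortLabels, GenotypeMatrix, LocusManifest, ValidationError
from .grs import GeneticRiskScorer, SCORE_TYPES
from .lmm import (
    GRM,
    association_scan,
    compute_grm,
    eigendecompose,
    fit_lmm_snp,
    reml_lambda,
)
from .qc import genomic_inflation, ld_prune, pca, qq_points
from .simulate import SimulatorConfig, simulate_cohort

logger = logging.getLogger(__name__)

CASE_SUBSETS = ("ALL_LADA", "GADA_ONLY", "GADA_IA2A")
PAIRWISE_GROUPS = ("T1D", "T2D", "LADA", "GADA_ONLY", "GADA_IA2A", "CONTROL")


@dataclass
class RunConfig:
    """Settings for one end-to-end run."""

    mode: str = "SIMULATE"
    sim: SimulatorConfig = field(default_factory=SimulatorConfig)
    genotype_path: str | None = None
    genotype_format: str = "dosage-TSV"
    manifest_path: str | None = None
    labels_path: str | None = None
    alpha: float = 0.05
    score_types: tuple[str, ...] = SCORE_TYPES
    case_subsets: tuple[str, ...] = CASE_SUBSETS
    or_mode: str = "EXPONENT"
    max_null_snps: int = 1000
    seed: int = 0
    outdir: str = "ladagrs_report"

    def __post_init__(self) -> None:
        if self.mode not in ("SIMULATE", "FILES"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if not self.score_types:
            raise ValidationError("score_types must be nonempty")
        if not self.case_subsets:
            raise ValidationError("case_subsets must be nonempty")
        bad = set(self.case_subsets) - set(CASE_SUBSETS)
        if bad:
            raise ValidationError(f"unknown case subsets {sorted(bad)}")


def _load_inputs(config: RunConfig):
    if config.mode == "SIMULATE":
        sim = replace(config.sim, seed=config.seed)
        return simulate_cohort(sim)
    manifest = io.read_manifest(config.manifest_path)
    G = io.read_genotypes(config.genotype_path, config.genotype_format, manifest)
    labels = io.read_labels(config.labels_path)
    return G, labels, manifest


def null_scan_pvalues(
    G: GenotypeMatrix,
    labels: CohortLabels,
    snp_ids: list[str],
    group_a: str,
    group_b: str,
    grm: GRM | None,
) -> np.ndarray:
    """Mixed-model p-values for a list of (background) SNPs."""
    mask = labels.group_mask(group_a, G.individual_ids) | labels.group_mask(
        group_b, G.individual_ids
    )
    Gu = G.subset_individuals(mask)
    y = labels.group_mask(group_a, Gu.individual_ids).astype(float)
    eig = None
    lam = None
    if grm is not None:
        keep = {iid: k for k, iid in enumerate(grm.individual_ids)}
        idx = [keep[iid] for iid in Gu.individual_ids]
        sub = GRM(grm.matrix[np.ix_(idx, idx)], Gu.individual_ids)
        eig = eigendecompose(sub)
        lam = reml_lambda(y, eig)
    ps = []
    for s in snp_ids:
        x = Gu.column(s)
        if np.ptp(x[~np.isnan(x)]) == 0:
            continue
        ps.append(fit_lmm_snp(y, x, eig, lam=lam).p)
    return np.asarray(ps)


def run_all(config: RunConfig) -> Path:
    """Run the full study on simulated or file-supplied data."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        G, labels, manifest = _load_inputs(config)

        stage = "qc"
        candidate = set(manifest.snp_ids)
        bg_ids = [s for s in G.snp_ids if s not in candidate]
        grm = None
        if bg_ids:
            G_bg = G.subset_snps(bg_ids)
            pruned = ld_prune(G_bg)
            G_pruned = G_bg.subset_snps(pruned)
            coords, explained = pca(G_pruned, k=2)
            pd.DataFrame(
                {
                    "individual_id": G.individual_ids,
                    "group": labels.aligned_to(G.individual_ids)["group"].to_numpy(),
                    "subpop": labels.aligned_to(G.individual_ids)["subpop"].to_numpy(),
                    "PC1": coords[:, 0],
                    "PC2": coords[:, 1],
                }
            ).to_csv(out / "pca.tsv", sep="\t", index=False)
            grm = compute_grm(G_pruned)
            null_ids = pruned[: config.max_null_snps]
            groups_present = set(labels.table["group"])
            ga, gb = ("LADA", "CONTROL") if {"LADA", "CONTROL"} <= groups_present \
                else tuple(sorted(groups_present))[:2]
            pvals = null_scan_pvalues(G, labels, null_ids, ga, gb, grm)
            infl = genomic_inflation(pvals)
            pd.DataFrame(
                [{"lambda_gc": infl.lambda_gc, "n_pvalues": infl.n_pvalues,
                  "pc1_explained": explained[0], "pc2_explained": explained[1]}]
            ).to_csv(out / "inflation.tsv", sep="\t", index=False)
            qq = qq_points(pvals)
            pd.DataFrame(qq, columns=["expected_neglog10p", "observed_neglog10p"]) \
                .to_csv(out / "qq.tsv", sep="\t", index=False)
        else:
            logger.warning("no background SNPs: skipping PCA/lambda, identity GRM")

        stage = "association"
        groups_present = set(labels.table["group"])
        contrasts = []
        for subset in config.case_subsets:
            if "CONTROL" in groups_present:
                contrasts.append(("T1D", subset, "CONTROL"))
                contrasts.append(("T2D", subset, "CONTROL"))
            if "T1D" in groups_present:
                contrasts.append(("T1D", subset, "T1D"))
            if "T2D" in groups_present:
                contrasts.append(("T2D", subset, "T2D"))
        for panel, subset, group_b in contrasts:
            records = association_scan(
                G, labels, manifest, "LADA", group_b,
                alpha=config.alpha, grm=grm, or_mode=config.or_mode,
                panel=panel, subset_a=None if subset == "ALL_LADA" else subset,
            )
            io.write_scan_results(
                records, out / f"assoc_{panel}_{subset}_vs_{group_b}.tsv"
            )

        stage = "grs"
        vectors = []
        for score_type in config.score_types:
            scorer = GeneticRiskScorer(manifest, score_type).fit()
            vectors.append(scorer.score_vector(G))
        from .grs import scores_to_frame

        score_frame = scores_to_frame(vectors, labels)
        io.write_scores(score_frame, out / "scores.tsv")

        stage = "classify"
        auc_rows = []
        control_mask = labels.group_mask("CONTROL", G.individual_ids)
        for v in vectors:
            for subset in config.case_subsets:
                case_mask = labels.subset_mask(subset, G.individual_ids)
                if not case_mask.any() or not control_mask.any():
                    continue
                mask = case_mask | control_mask
                roc = roc_auc(
                    v.scores.to_numpy()[mask], case_mask[mask].astype(int)
                )
                auc_rows.append(
                    {
                        "score_type": v.score_type,
                        "case_subset": subset,
                        "n_cases": int(case_mask.sum()),
                        "n_controls": int(control_mask.sum()),
                        "auc": roc.auc,
                    }
                )
                pd.DataFrame(
                    {
                        "threshold": roc.thresholds,
                        "sensitivity": roc.sensitivity,
                        "one_minus_specificity": roc.one_minus_specificity,
                    }
                ).to_csv(out / f"roc_{v.score_type}_{subset}.tsv", sep="\t",
                         index=False)
        pd.DataFrame(auc_rows).to_csv(out / "auc_summary.tsv", sep="\t", index=False)

        for v in vectors:
            if v.score_type not in ("T1D", "T2D"):
                continue
            by_group = {}
            for gname in PAIRWISE_GROUPS:
                if gname in ("GADA_ONLY", "GADA_IA2A"):
                    mask = labels.subset_mask(gname, G.individual_ids)
                elif gname == "LADA":
                    mask = labels.subset_mask("ALL_LADA", G.individual_ids)
                else:
                    mask = labels.group_mask(gname, G.individual_ids)
                if mask.sum() >= 2:
                    by_group[gname] = v.scores.to_numpy()[mask]
            if len(by_group) >= 2:
                matrix = pairwise_rank_tests(by_group)
                matrix.to_frame().to_csv(
                    out / f"pairwise_{v.score_type}.tsv", sep="\t", index=False
                )

        stage = "log"
        import scipy
        import sklearn
        import statsmodels

        log_lines = [
            f"ladagrs {__version__}",
            f"numpy {np.__version__}; scipy {scipy.__version__}; "
            f"pandas {pd.__version__}; statsmodels {statsmodels.__version__}; "
            f"scikit-learn {sklearn.__version__}",
            f"seed: {config.seed}",
            "config:",
            yaml.safe_dump(_config_echo(config), sort_keys=True),
        ]
        (out / "run_log.txt").write_text("\n".join(log_lines))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def _config_echo(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["sim"] = config.sim.to_dict() if config.mode == "SIMULATE" else None
    if d["sim"] is not None:
        d["sim"].pop("manifest", None)
    d["score_types"] = list(config.score_types)
    d["case_subsets"] = list(config.case_subsets)
    d["outdir"] = str(config.outdir)
    return d
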