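"""Weighted genetic risk scores with HLA tag-SNP diplotype handling.

A score is the sum over panel loci of risk-allele dosage times
ln(published OR).  Panel membership follows the manifest: loci
implicated in both diseases and loci without a published OR never enter
a score.  The two HLA class II tag SNPs (DR3 and DR4-DQ8) can either be
weighted additively (default) or replaced by a diplotype-category weight
inferred from their joint dosages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import (
    CohortLabels,
    GenotypeMatrix,
    LocusManifest,
    ValidationError,
)

logger = logging.getLogger(__name__)

SCORE_TYPES = ("T1D", "T2D", "COMBINED", "T1D_NO_HLA", "HLA_ONLY")

DIPLOTYPE_CATEGORIES = (
    "DR3/DR3", "DR3/DR4", "DR4/DR4", "DR3/X", "DR4/X", "X/X", "INCONSISTENT",
)


def select_grs_snps(manifest: LocusManifest, score_type: str) -> LocusManifest:
    """Apply the panel and exclusion rules for one score type.

    Retained: SNPs of the requested panel(s) with a published OR.
    Dropped always: panel BOTH.  T1D_NO_HLA additionally drops every
    HLA-tagged locus; HLA_ONLY keeps only HLA-tagged loci.
    """
    if score_type not in SCORE_TYPES:
        raise ValidationError(f"unknown score type {score_type!r}")
    panels = {
        "T1D": {"T1D"},
        "T1D_NO_HLA": {"T1D"},
        "HLA_ONLY": {"T1D", "T2D"},
        "T2D": {"T2D"},
        "COMBINED": {"T1D", "T2D"},
    }[score_type]
    records = [
        r
        for r in manifest
        if r.disease_panel in panels and r.published_or is not None
    ]
    if score_type == "T1D_NO_HLA":
        records = [r for r in records if r.hla_role == "NONE"]
    elif score_type == "HLA_ONLY":
        records = [r for r in records if r.hla_role != "NONE"]
    if not records:
        raise ValidationError(f"no loci eligible for score type {score_type}")
    return manifest.subset([r.snp_id for r in records])


def infer_hla_diplotype(dr3_tag_dosage, dr4_tag_dosage) -> str | None:
    """HLA DR3/DR4-DQ8 diplotype category from the two tag-SNP dosages.

    Returns None when either dosage is missing (unresolvable), so scoring
    can fall back to additive tag weighting.
    """
    if dr3_tag_dosage is None or dr4_tag_dosage is None:
        return None
    d3, d4 = float(dr3_tag_dosage), float(dr4_tag_dosage)
    if math.isnan(d3) or math.isnan(d4):
        return None
    if d3 + d4 > 2:
        return "INCONSISTENT"
    key = (int(d3), int(d4))
    return {
        (2, 0): "DR3/DR3",
        (1, 1): "DR3/DR4",
        (0, 2): "DR4/DR4",
        (1, 0): "DR3/X",
        (0, 1): "DR4/X",
        (0, 0): "X/X",
    }[key]


@dataclass
class GRSWeightSet:
    """Per-SNP ln(OR) weights for one score type.

    ``hla_diplotype_weights`` optionally maps diplotype categories to a
    weight that replaces the additive contribution of the two tag SNPs.
    """

    score_type: str
    weights: dict[str, float]
    hla_diplotype_weights: dict[str, float] | None = None
    dr3_tag_snp: str | None = None
    dr4_tag_snp: str | None = None

    def __post_init__(self) -> None:
        for snp, w in self.weights.items():
            if not math.isfinite(w):
                raise ValidationError(f"non-finite weight for {snp}")
        if self.hla_diplotype_weights is not None and (
            self.dr3_tag_snp is None or self.dr4_tag_snp is None
        ):
            raise ValidationError(
                "diplotype weighting requires both tag SNP ids"
            )

    @classmethod
    def from_manifest(
        cls,
        manifest: LocusManifest,
        score_type: str,
        hla_diplotype_weights: Mapping[str, float] | None = None,
    ) -> "GRSWeightSet":
        subset = select_grs_snps(manifest, score_type)
        weights = {r.snp_id: math.log(r.published_or) for r in subset}
        dr3 = next((r.snp_id for r in subset if r.hla_role == "DR3_TAG"), None)
        dr4 = next((r.snp_id for r in subset if r.hla_role == "DR4_TAG"), None)
        dip = dict(hla_diplotype_weights) if hla_diplotype_weights else None
        if dip is not None and (dr3 is None or dr4 is None):
            dip = None  # both tags needed for diplotype inference
        return cls(score_type, weights, dip, dr3, dr4)


@dataclass
class ScoreVector:
    """Per-individual GRS of a given score type."""

    scores: pd.Series
    score_type: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise ValidationError("scores must be finite")

    def values_for(self, individual_ids: Sequence[str]) -> np.ndarray:
        return self.scores.loc[list(individual_ids)].to_numpy(dtype=float)


def compute_grs(
    G: GenotypeMatrix,
    w: GRSWeightSet,
    labels: CohortLabels | None = None,
    missing_policy: str = "impute_freq",
) -> ScoreVector:
    """Score every individual: sum of dosage * ln(OR) over weighted loci.

    Missing dosages are imputed as 2 * (scored-sample risk-allele
    frequency) by default; ``missing_policy="omit_rescale"`` instead
    omits missing loci and rescales each score by the ratio of total to
    observed weight sum.  When diplotype weights are configured, the two
    tag SNPs contribute through their inferred category; individuals with
    an unresolvable or INCONSISTENT category fall back to additive tag
    weighting with a logged warning.
    """
    present = set(G.snp_ids.tolist())
    missing_snps = [s for s in w.weights if s not in present]
    if missing_snps:
        raise ValidationError(f"weighted SNPs absent from genotypes: {missing_snps}")
    use_diplotype = w.hla_diplotype_weights is not None
    additive_snps = [
        s for s in w.weights
        if not (use_diplotype and s in (w.dr3_tag_snp, w.dr4_tag_snp))
    ]
    X = np.column_stack([G.column(s) for s in additive_snps]) \
        if additive_snps else np.zeros((G.n_individuals, 0))
    wts = np.array([w.weights[s] for s in additive_snps])
    freqs = np.nanmean(X, axis=0) / 2.0 if X.size else np.zeros(0)

    if missing_policy == "impute_freq":
        Xf = np.where(np.isnan(X), 2.0 * freqs, X)
        scores = Xf @ wts
    elif missing_policy == "omit_rescale":
        obs = ~np.isnan(X)
        raw = np.where(obs, X, 0.0) @ wts
        total_w = np.abs(wts).sum()
        obs_w = obs @ np.abs(wts)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(obs_w > 0, total_w / obs_w, 0.0)
        scores = raw * scale
    else:
        raise ValidationError(f"unknown missing policy {missing_policy!r}")

    if use_diplotype:
        d3 = G.column(w.dr3_tag_snp)
        d4 = G.column(w.dr4_tag_snp)
        f3 = np.nanmean(d3) / 2.0
        f4 = np.nanmean(d4) / 2.0
        n_fallback = 0
        for i in range(G.n_individuals):
            cat = infer_hla_diplotype(d3[i], d4[i])
            if cat is None or cat == "INCONSISTENT" or cat not in w.hla_diplotype_weights:
                x3 = d3[i] if not math.isnan(d3[i]) else 2.0 * f3
                x4 = d4[i] if not math.isnan(d4[i]) else 2.0 * f4
                scores[i] += x3 * w.weights[w.dr3_tag_snp] + x4 * w.weights[w.dr4_tag_snp]
                n_fallback += 1
            else:
                scores[i] += w.hla_diplotype_weights[cat]
        if n_fallback:
            logger.warning(
                "%d individual(s) fell back to additive HLA tag weighting",
                n_fallback,
            )
    series = pd.Series(scores, index=pd.Index(G.individual_ids, name="individual_id"))
    return ScoreVector(series, w.score_type)


def scores_to_frame(
    vectors: Sequence[ScoreVector], labels: CohortLabels
) -> pd.DataFrame:
    """Long-format score table: individual_id, group, gada, ia2a, score_type, score."""
    frames = []
    for v in vectors:
        tbl = labels.aligned_to(v.scores.index)
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": v.scores.index,
                    "group": tbl["group"].to_numpy(),
                    "gada": tbl["gada"].to_numpy(),
                    "ia2a": tbl["ia2a"].to_numpy(),
                    "score_type": v.score_type,
                    "score": v.scores.to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class GeneticRiskScorer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: genotype matrix -> risk-score column.

    Parameters
    ----------
    manifest : LocusManifest
        Locus metadata carrying the published ORs.
    score_type : str
        One of T1D, T2D, COMBINED, T1D_NO_HLA, HLA_ONLY.
    hla_diplotype_weights : mapping or None
        Optional diplotype-category weights replacing additive tag SNPs.
    missing_policy : {"impute_freq", "omit_rescale"}

    ``fit`` freezes the weight set; ``transform`` accepts a
    GenotypeMatrix and returns an (n, 1) array of scores.
    """

    def __init__(
        self,
        manifest: LocusManifest,
        score_type: str = "T1D",
        hla_diplotype_weights: Mapping[str, float] | None = None,
        missing_policy: str = "impute_freq",
    ):
        self.manifest = manifest
        self.score_type = score_type
        self.hla_diplotype_weights = hla_diplotype_weights
        self.missing_policy = missing_policy

    def fit(self, X: GenotypeMatrix | None = None, y=None):
        self.weight_set_ = GRSWeightSet.from_manifest(
            self.manifest, self.score_type, self.hla_diplotype_weights
        )
        return self

    def transform(self, X: GenotypeMatrix) -> np.ndarray:
        if not hasattr(self, "weight_set_"):
            self.fit()
        vec = compute_grs(X, self.weight_set_, missing_policy=self.missing_policy)
        return vec.scores.to_numpy()[:, None]

    def score_vector(self, X: GenotypeMatrix) -> ScoreVector:
        if not hasattr(self, "weight_set_"):
            self.fit()
        return compute_grs(X, self.weight_set_, missing_policy=self.missing_policy)
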