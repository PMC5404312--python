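"""Structured cohort simulator.

Generates genotype matrices and labels with the statistical structure the
downstream analysis assumes: group-specific risk-allele frequencies at
candidate loci, background SNPs for relatedness/PCA/inflation estimation,
two-subpopulation differentiation under the Balding-Nichols model,
sib-pair relatedness, batch-wise missingness, and antibody-defined LADA
subsets (GADA-only and GADA+IA2A+).

Default group sizes are 978 LADA, 1057 controls, 2000 T1D and 1960 T2D,
with the LADA group split 669 GADA-only / 309 GADA+IA2A+.  The default
candidate-locus panel carries the loci with published group frequencies
(MHC, PTPN22, SH2B3, the two INS signals, SMARCE1, HNF1A, TCF7L2, ZBED3,
the HLA DR3/DR4-DQ8 tag SNPs and the conventionally excluded loci).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .containers import (
    CohortLabels,
    GenotypeMatrix,
    GROUPS,
    LocusManifest,
    LocusRecord,
    ValidationError,
)

# Candidate-locus presets: group frequencies of the risk allele and the
# odds ratio used as the scoring weight.  Loci with a reported OR < 1 are
# stored already re-oriented to the risk-increasing allele.  Frequencies
# for (locus, group) pairs never reported are realistic European values
# chosen once (see docs/methods.md).
# Columns: snp, chrom, pos, risk, other, panel, OR (None = unavailable),
# hla_role, {group or LADA subset: frequency}.
_PRESETS = [
    ("rs9272346", "6", 32604372, "A", "G", "T1D", 1.455, "HLA_OTHER",
     {"LADA": 0.686, "T1D": 0.818, "CONTROL": 0.579, "T2D": 0.579,
      "LADA_GADA_IA2A": 0.763}),
    ("rs6679677", "1", 114303808, "A", "C", "T1D", 1.469, "NONE",
     {"LADA": 0.143, "T1D": 0.17, "CONTROL": 0.093, "T2D": 0.093,
      "LADA_GADA_IA2A": 0.17}),
    ("rs17696736", "12", 112486818, "G", "A", "T1D", 1.277, "NONE",
     {"LADA": 0.515, "T1D": 0.503, "CONTROL": 0.44, "T2D": 0.44,
      "LADA_GADA_IA2A": 0.542}),
    ("rs689", "11", 2182224, "T", "A", "T1D", 1.265, "NONE",
     {"LADA": 0.796, "T1D": 0.741, "CONTROL": 0.73, "T2D": 0.73,
      "LADA_GADA_IA2A": 0.824}),
    ("rs7111341", "11", 2126719, "C", "T", "T1D", None, "NONE",
     {"LADA": 0.79, "T1D": 0.75, "CONTROL": 0.73, "T2D": 0.73,
      "LADA_GADA_IA2A": 0.812}),
    # SMARCE1: reported protective (OR 0.954 for C); stored for the T allele.
    ("rs7221109", "17", 38775150, "T", "C", "T1D", 1 / 0.954, "NONE",
     {"LADA": 0.379, "T1D": 0.313, "CONTROL": 0.368, "T2D": 0.368,
      "LADA_GADA_IA2A": 0.379}),
    # HLA class II tag SNPs (DR3 and DR4-DQ8 haplotype tags).
    ("rs2187668", "6", 32605884, "A", "G", "T1D", 2.5, "DR3_TAG",
     {"LADA": 0.22, "T1D": 0.30, "CONTROL": 0.12, "T2D": 0.12,
      "LADA_GADA_IA2A": 0.28}),
    ("rs7454108", "6", 32681049, "C", "T", "T1D", 2.0, "DR4_TAG",
     {"LADA": 0.18, "T1D": 0.27, "CONTROL": 0.10, "T2D": 0.10,
      "LADA_GADA_IA2A": 0.25}),
    # No public OR; exercised by the exclusion rule.
    ("rs11171710", "12", 56470625, "A", "G", "T1D", None, "NONE",
     {"LADA": 0.62, "T1D": 0.64, "CONTROL": 0.60, "T2D": 0.60}),
    ("rs12427353", "12", 121426901, "G", "C", "T2D", 1.291, "NONE",
     {"LADA": 0.831, "T2D": 0.828, "CONTROL": 0.787, "T1D": 0.787,
      "LADA_GADA_IA2A": 0.857}),
    ("rs7903146", "10", 114758349, "T", "C", "T2D", 1.37, "NONE",
     {"LADA": 0.295, "T2D": 0.376, "CONTROL": 0.298, "T1D": 0.298,
      "LADA_GADA_IA2A": 0.251}),
    ("rs6878122", "5", 76435004, "A", "G", "T2D", 1.08, "NONE",
     {"LADA": 0.72, "T2D": 0.658, "CONTROL": 0.706, "T1D": 0.706,
      "LADA_GADA_IA2A": 0.744}),
    # Implicated in both diseases; exercised by the panel-BOTH exclusion.
    ("rs7202877", "16", 75247245, "T", "G", "BOTH", 1.3, "NONE",
     {"LADA": 0.9, "T1D": 0.91, "CONTROL": 0.89, "T2D": 0.89}),
]

# The two INS signals are partially correlated; r^2 target for the
# optional LD pair.
INS_LD_PAIR = ("rs689", "rs7111341", 0.278)

DEFAULT_GROUP_SIZES = {"LADA": 978, "CONTROL": 1057, "T1D": 2000, "T2D": 1960}
DEFAULT_ANTIBODY_SPLIT = (669 / 978, 309 / 978)  # (GADA-only, GADA+IA2A+)


def preset_manifest() -> LocusManifest:
    """The built-in candidate-locus manifest."""
    return LocusManifest(
        [
            LocusRecord(snp, chrom, pos, risk, other, panel, orr, hla)
            for snp, chrom, pos, risk, other, panel, orr, hla, _ in _PRESETS
        ]
    )


def preset_candidate_freqs() -> dict[str, dict[str, float]]:
    """Per-locus group (and LADA-subset) risk-allele frequencies."""
    return {snp: dict(freqs) for snp, *_, freqs in _PRESETS}


@dataclass
class SimulatorConfig:
    """Cohort simulator settings; defaults mirror the study layout."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    antibody_split: tuple[float, float] = DEFAULT_ANTIBODY_SPLIT
    candidate_freqs: dict[str, dict[str, float]] = field(
        default_factory=preset_candidate_freqs
    )
    manifest: LocusManifest = field(default_factory=preset_manifest)
    n_background_snps: int = 5000
    background_freq_range: tuple[float, float] = (0.05, 0.95)
    fst: float = 0.0
    n_subpops: int = 1
    subpop_group_bias: float = 0.0
    related_pair_fraction: float = 0.0
    batch_missing_rates: dict[str, float] = field(
        default_factory=lambda: {"batch0": 0.0}
    )
    ld_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    antibody_enrichment: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValidationError(f"unknown group {g!r}")
            if n < 1:
                raise ValidationError(f"group size for {g} must be positive")
        if abs(sum(self.antibody_split) - 1.0) > 1e-9:
            raise ValidationError("antibody_split fractions must sum to 1")
        if not 0.0 <= self.fst < 1.0:
            raise ValidationError("fst must be in [0, 1)")
        if self.n_subpops < 1:
            raise ValidationError("n_subpops must be >= 1")
        if not 0.0 <= self.subpop_group_bias < 1.0:
            raise ValidationError("subpop_group_bias must be in [0, 1)")
        lo, hi = self.background_freq_range
        if not (0.05 <= lo < hi <= 0.95):
            raise ValidationError("background_freq_range must lie within (0.05, 0.95)")
        if not 0.0 <= self.related_pair_fraction <= 1.0:
            raise ValidationError("related_pair_fraction must be in [0, 1]")
        if self.n_background_snps < 0:
            raise ValidationError("n_background_snps must be >= 0")
        for snp, by_group in self.candidate_freqs.items():
            for g, p in by_group.items():
                if not 0.0 <= p <= 1.0:
                    raise ValidationError(f"frequency for ({snp}, {g}) outside [0, 1]")
        for rate in self.batch_missing_rates.values():
            if not 0.0 <= rate < 1.0:
                raise ValidationError("missingness rates must be in [0, 1)")

    # -- flat-file round trip ------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "group_sizes": dict(self.group_sizes),
            "antibody_split": list(self.antibody_split),
            "candidate_freqs": {
                s: dict(v) for s, v in self.candidate_freqs.items()
            },
            "n_background_snps": self.n_background_snps,
            "background_freq_range": list(self.background_freq_range),
            "fst": self.fst,
            "n_subpops": self.n_subpops,
            "subpop_group_bias": self.subpop_group_bias,
            "related_pair_fraction": self.related_pair_fraction,
            "batch_missing_rates": dict(self.batch_missing_rates),
            "ld_pairs": [list(p) for p in self.ld_pairs],
            "antibody_enrichment": self.antibody_enrichment,
            "seed": self.seed,
        }
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulatorConfig":
        kwargs = dict(d)
        if "antibody_split" in kwargs:
            kwargs["antibody_split"] = tuple(kwargs["antibody_split"])
        if "background_freq_range" in kwargs:
            kwargs["background_freq_range"] = tuple(kwargs["background_freq_range"])
        if "ld_pairs" in kwargs:
            kwargs["ld_pairs"] = [tuple(p) for p in kwargs["ld_pairs"]]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulatorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def sample_genotypes(
    freqs: Sequence[float], n: int, seed: int | np.random.Generator = 0
) -> GenotypeMatrix:
    """Hardy-Weinberg dosage sampling: Binomial(2, p) per locus.

    Returns an ``n x len(freqs)`` genotype matrix with no missing calls.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim != 1:
        raise ValidationError("freqs must be a 1-D vector")
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValidationError("allele frequencies must lie in [0, 1]")
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    dosages = rng.binomial(2, freqs, size=(n, freqs.size)).astype(float)
    ind = np.array([f"ind{i:05d}" for i in range(n)], dtype=object)
    snps = np.array([f"snp{j:05d}" for j in range(freqs.size)], dtype=object)
    return GenotypeMatrix(ind, snps, dosages)


def drift_frequencies(
    base_freqs: Sequence[float],
    fst: float,
    n_subpops: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Balding-Nichols subpopulation frequencies.

    Each subpopulation frequency is drawn from
    Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean p and variance
    F p (1-p).  With F = 0 the base frequencies are returned unchanged.
    Returns an ``n_subpops x m`` array.
    """
    base = np.asarray(base_freqs, dtype=float)
    if not 0.0 <= fst < 1.0:
        raise ValidationError("fst must be in [0, 1)")
    if fst == 0.0:
        return np.tile(base, (n_subpops, 1))
    if np.any((base <= 0.0) | (base >= 1.0)):
        raise ValidationError("base frequencies must be in (0, 1) when fst > 0")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    scale = (1.0 - fst) / fst
    return rng.beta(base * scale, (1.0 - base) * scale, size=(n_subpops, base.size))


def assign_status_logistic(
    genotypes: GenotypeMatrix,
    weights: Sequence[float],
    intercept: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sample binary status with P(case) = logistic(intercept + G @ w)."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (genotypes.n_snps,):
        raise ValidationError(
            f"weights length {w.size} does not match {genotypes.n_snps} loci"
        )
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    eta = intercept + np.nan_to_num(genotypes.dosages) @ w
    prob = 1.0 / (1.0 + np.exp(-eta))
    return (rng.random(genotypes.n_individuals) < prob).astype(int)


def _mix_proportion(r2: float, p_a: float, p_b: float) -> float:
    """Copy probability m so cor(allele_a, allele_b) hits sqrt(r2).

    With allele_b copied from allele_a with probability m (else drawn at
    p_b): cov = m p_a (1 - p_b), so m = r sd_a sd_b / (p_a (1 - p_b)).
    """
    r = math.sqrt(r2)
    sd = math.sqrt(p_a * (1 - p_a) * p_b * (1 - p_b))
    m = r * sd / (p_a * (1 - p_b))
    return min(1.0, m)


def _sample_pair_haplotypes(
    rng: np.random.Generator, p_a: float, p_b: float, m: float, shape
) -> tuple[np.ndarray, np.ndarray]:
    a = (rng.random(shape) < p_a).astype(float)
    b_indep = (rng.random(shape) < p_b).astype(float)
    copy = rng.random(shape) < m
    return a, np.where(copy, a, b_indep)


def _resolve_subset_freq(
    by_group: Mapping[str, float],
    subset: str,
    n_all: int,
    n_go: int,
    n_ri: int,
) -> float:
    """Frequency for a LADA antibody subset.

    Uses an explicit subset entry when configured; otherwise, if only the
    overall LADA and GADA+IA2A+ frequencies are given, the GADA-only
    frequency is recovered by mixture inversion so the pooled LADA
    frequency matches its configured value.
    """
    if subset in by_group:
        return by_group[subset]
    f_all = by_group["LADA"]
    if subset == "LADA_GADA_ONLY" and "LADA_GADA_IA2A" in by_group and n_go > 0:
        f_ri = by_group["LADA_GADA_IA2A"]
        f_go = (f_all * n_all - f_ri * n_ri) / n_go
        return float(np.clip(f_go, 0.0, 1.0))
    return f_all


def simulate_cohort(
    config: SimulatorConfig,
) -> tuple[GenotypeMatrix, CohortLabels, LocusManifest]:
    """Simulate the full cohort: candidates + background SNPs + labels.

    Candidate loci are sampled at group-specific frequencies (LADA
    antibody subsets at their own frequencies when configured);
    background SNPs share frequencies across groups, drifted per
    subpopulation when ``fst > 0``.  Sib-pair blocks share parentally
    sampled haplotypes; missingness is applied per batch afterwards.
    Fully reproducible from ``config.seed``.
    """
    manifest = config.manifest
    for rec in manifest:
        if rec.snp_id not in config.candidate_freqs:
            raise ValidationError(f"candidate_freqs missing locus {rec.snp_id}")
        by_group = config.candidate_freqs[rec.snp_id]
        for g in config.group_sizes:
            if g not in by_group:
                raise ValidationError(
                    f"candidate_freqs missing pair ({rec.snp_id}, {g})"
                )

    ss = np.random.SeedSequence(config.seed)
    (s_struct, s_cand, s_bg, s_anti, s_batch, s_miss) = ss.spawn(6)
    rng_struct = np.random.default_rng(s_struct)
    rng_cand = np.random.default_rng(s_cand)
    rng_bg = np.random.default_rng(s_bg)
    rng_anti = np.random.default_rng(s_anti)
    rng_batch = np.random.default_rng(s_batch)
    rng_miss = np.random.default_rng(s_miss)

    groups_order = [g for g in ("CONTROL", "T1D", "T2D", "LADA") if g in config.group_sizes]
    group_of: list[str] = []
    for g in groups_order:
        group_of.extend([g] * config.group_sizes[g])
    n_total = len(group_of)
    group_of = np.asarray(group_of, dtype=object)
    individual_ids = np.array([f"ind{i:05d}" for i in range(n_total)], dtype=object)

    # Subpopulation assignment (sib pairs share); sib blocks within group.
    # A nonzero subpop_group_bias makes controls favor subpopulation 0,
    # emulating case/control cohorts ascertained from different strata.
    k = config.n_subpops
    if k > 1 and config.subpop_group_bias > 0:
        b = config.subpop_group_bias
        p_control = np.full(k, (1.0 - (1.0 / k + b * (1 - 1.0 / k))) / (k - 1))
        p_control[0] = 1.0 / k + b * (1 - 1.0 / k)
        p_case = np.full(k, (1.0 - (1.0 / k) * (1 - b)) / (k - 1))
        p_case[0] = (1.0 / k) * (1 - b)
        subpop = np.empty(n_total, dtype=int)
        is_control = group_of == "CONTROL"
        subpop[is_control] = rng_struct.choice(
            k, size=int(is_control.sum()), p=p_control
        )
        subpop[~is_control] = rng_struct.choice(
            k, size=int((~is_control).sum()), p=p_case
        )
    else:
        subpop = rng_struct.integers(k, size=n_total)
    sib_partner = np.full(n_total, -1, dtype=int)
    for g in groups_order:
        idx = np.flatnonzero(group_of == g)
        n_pairs = int(config.related_pair_fraction * idx.size) // 2
        if n_pairs:
            chosen = rng_struct.choice(idx, size=2 * n_pairs, replace=False)
            for k in range(n_pairs):
                i, j = chosen[2 * k], chosen[2 * k + 1]
                sib_partner[i], sib_partner[j] = j, i
                subpop[j] = subpop[i]

    # LADA antibody subsets.
    gada = np.zeros(n_total, dtype=bool)
    ia2a = np.zeros(n_total, dtype=bool)
    lada_idx = np.flatnonzero(group_of == "LADA")
    n_lada = lada_idx.size
    n_ri = int(round(config.antibody_split[1] * n_lada)) if n_lada else 0
    n_go = n_lada - n_ri
    shuffled = rng_anti.permutation(lada_idx)
    ri_set = shuffled[:n_ri]
    go_set = shuffled[n_ri:]
    gada[lada_idx] = True
    ia2a[ri_set] = True

    # Per-individual candidate frequency: group, or LADA subset.
    m_cand = len(manifest)
    freq_matrix = np.empty((n_total, m_cand))
    for j, rec in enumerate(manifest):
        by_group = config.candidate_freqs[rec.snp_id]
        col = np.empty(n_total)
        for g in groups_order:
            col[group_of == g] = by_group[g]
        if n_lada:
            col[ri_set] = _resolve_subset_freq(
                by_group, "LADA_GADA_IA2A", n_lada, n_go, n_ri
            )
            col[go_set] = _resolve_subset_freq(
                by_group, "LADA_GADA_ONLY", n_lada, n_go, n_ri
            )
        freq_matrix[:, j] = col

    cand = _sample_with_sibs(rng_cand, freq_matrix, sib_partner)

    # Optional LD pairs: regenerate the pair haplotype-wise with copying.
    snp_pos = {s: j for j, s in enumerate(manifest.snp_ids)}
    for snp_a, snp_b, r2 in config.ld_pairs:
        ja, jb = snp_pos[snp_a], snp_pos[snp_b]
        pa, pb = freq_matrix[:, ja], freq_matrix[:, jb]
        m = np.array(
            [_mix_proportion(r2, a, b) if 0 < a < 1 and 0 < b < 1 else 0.0
             for a, b in zip(pa, pb)]
        )
        h_a = (rng_cand.random((n_total, 2)) < pa[:, None]).astype(float)
        b_indep = (rng_cand.random((n_total, 2)) < pb[:, None]).astype(float)
        copy = rng_cand.random((n_total, 2)) < m[:, None]
        h_b = np.where(copy, h_a, b_indep)
        cand[:, ja] = h_a.sum(axis=1)
        cand[:, jb] = h_b.sum(axis=1)

    # Background SNPs: shared base frequencies, optionally drifted.
    lo, hi = config.background_freq_range
    base = rng_bg.uniform(lo, hi, size=config.n_background_snps)
    if config.n_subpops > 1 and config.fst > 0:
        per_pop = drift_frequencies(base, config.fst, config.n_subpops, rng_bg)
    else:
        per_pop = np.tile(base, (config.n_subpops, 1))
    bg_freq_matrix = per_pop[subpop]
    background = _sample_with_sibs(rng_bg, bg_freq_matrix, sib_partner)

    dosages = np.concatenate([cand, background], axis=1)
    snp_ids = np.concatenate(
        [
            np.asarray(manifest.snp_ids, dtype=object),
            np.array([f"bg{j:05d}" for j in range(config.n_background_snps)],
                     dtype=object),
        ]
    )

    # Optional enrichment: GADA+IA2A+ membership follows T1D-panel liability.
    if config.antibody_enrichment and n_lada:
        t1d_cols = [
            snp_pos[r.snp_id]
            for r in manifest
            if r.disease_panel == "T1D" and r.published_or is not None
        ]
        w = np.array(
            [math.log(r.published_or) for r in manifest
             if r.disease_panel == "T1D" and r.published_or is not None]
        )
        liability = cand[lada_idx][:, t1d_cols] @ w
        order = lada_idx[np.argsort(-liability, kind="stable")]
        gada[:] = False
        ia2a[:] = False
        gada[lada_idx] = True
        ia2a[order[:n_ri]] = True

    # Batch assignment and MCAR missingness per batch.
    batch_names = sorted(config.batch_missing_rates)
    batch = np.asarray(batch_names, dtype=object)[
        rng_batch.integers(len(batch_names), size=n_total)
    ]
    for name in batch_names:
        rate = config.batch_missing_rates[name]
        if rate > 0:
            rows = np.flatnonzero(batch == name)
            mask = rng_miss.random((rows.size, dosages.shape[1])) < rate
            block = dosages[rows]
            block[mask] = np.nan
            dosages[rows] = block

    G = GenotypeMatrix(individual_ids, snp_ids, dosages)
    labels = CohortLabels.from_arrays(
        individual_ids.tolist(),
        group_of.tolist(),
        gada=gada.tolist(),
        ia2a=ia2a.tolist(),
        subpop=subpop.tolist(),
        batch=batch.tolist(),
    )
    return G, labels, manifest


def _sample_with_sibs(
    rng: np.random.Generator, freq_matrix: np.ndarray, sib_partner: np.ndarray
) -> np.ndarray:
    """Binomial(2, p) dosages; sib pairs drawn from shared parental haplotypes."""
    n, m = freq_matrix.shape
    dosages = rng.binomial(2, freq_matrix).astype(float)
    done = np.zeros(n, dtype=bool)
    for i in range(n):
        j = sib_partner[i]
        if j < 0 or done[i]:
            continue
        p = freq_matrix[i]
        # Two parents, two haplotypes each; each sib inherits one haplotype
        # per parent, independently per locus.
        parents = (rng.random((2, 2, m)) < p).astype(float)
        for sib in (i, j):
            pick_m = rng.integers(2, size=m)
            pick_f = rng.integers(2, size=m)
            dosages[sib] = (
                parents[0][pick_m, np.arange(m)] + parents[1][pick_f, np.arange(m)]
            )
        done[i] = done[j] = True
    return dosages
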