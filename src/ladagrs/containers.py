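"""Core in-memory containers: locus manifest, genotype matrix, cohort labels.

Dosages are stored as a dense float array of risk-allele counts with
``numpy.nan`` marking missing calls; all non-missing entries are 0, 1 or 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("CONTROL", "T1D", "T2D", "LADA")
DISEASE_PANELS = ("T1D", "T2D", "BOTH")
HLA_ROLES = ("NONE", "DR3_TAG", "DR4_TAG", "HLA_OTHER")
CASE_SUBSETS = ("ALL_LADA", "GADA_ONLY", "GADA_IA2A")

_VALID_BASES = frozenset("ACGT")


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass(frozen=True)
class LocusRecord:
    """Per-SNP metadata: alleles, disease panel, published OR, HLA tag role."""

    snp_id: str
    chromosome: str
    position: int
    risk_allele: str
    other_allele: str
    disease_panel: str
    published_or: float | None = None
    hla_role: str = "NONE"

    def __post_init__(self) -> None:
        if self.risk_allele not in _VALID_BASES:
            raise ValidationError(
                f"{self.snp_id}: malformed risk allele {self.risk_allele!r}"
            )
        if self.other_allele not in _VALID_BASES:
            raise ValidationError(
                f"{self.snp_id}: malformed other allele {self.other_allele!r}"
            )
        if self.risk_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: risk and other allele identical")
        if self.position < 1:
            raise ValidationError(f"{self.snp_id}: position must be >= 1")
        if self.disease_panel not in DISEASE_PANELS:
            raise ValidationError(
                f"{self.snp_id}: unknown disease panel {self.disease_panel!r}"
            )
        if self.hla_role not in HLA_ROLES:
            raise ValidationError(f"{self.snp_id}: unknown HLA role {self.hla_role!r}")
        if self.published_or is not None and not self.published_or > 0:
            raise ValidationError(f"{self.snp_id}: published OR must be > 0")

    @property
    def is_strand_ambiguous(self) -> bool:
        """A/T and C/G SNPs cannot be strand-resolved from alleles alone."""
        return {self.risk_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})

    def flipped(self) -> "LocusRecord":
        """Swap alleles and invert the OR (same locus, other allele counted)."""
        return replace(
            self,
            risk_allele=self.other_allele,
            other_allele=self.risk_allele,
            published_or=None if self.published_or is None else 1.0 / self.published_or,
        )


class LocusManifest:
    """Ordered collection of :class:`LocusRecord` with unique SNP ids."""

    def __init__(self, records: Sequence[LocusRecord]):
        ids = [r.snp_id for r in records]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValidationError(f"duplicate snp_id(s): {sorted(dup)}")
        self._records = list(records)
        self._by_id = {r.snp_id: r for r in self._records}

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[LocusRecord]:
        return iter(self._records)

    def __getitem__(self, snp_id: str) -> LocusRecord:
        return self._by_id[snp_id]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._by_id

    def __eq__(self, other: object) -> bool:
        return isinstance(other, LocusManifest) and self._records == other._records

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self._records]

    def subset(self, snp_ids: Sequence[str]) -> "LocusManifest":
        keep = set(snp_ids)
        return LocusManifest([r for r in self._records if r.snp_id in keep])

    def panel(self, disease_panel: str) -> "LocusManifest":
        return LocusManifest(
            [r for r in self._records if r.disease_panel == disease_panel]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": [r.snp_id for r in self._records],
                "chromosome": [r.chromosome for r in self._records],
                "position": [r.position for r in self._records],
                "risk_allele": [r.risk_allele for r in self._records],
                "other_allele": [r.other_allele for r in self._records],
                "disease_panel": [r.disease_panel for r in self._records],
                "published_or": [r.published_or for r in self._records],
                "hla_role": [r.hla_role for r in self._records],
            }
        )


@dataclass
class GenotypeMatrix:
    """Individuals x loci risk-allele dosages in {0, 1, 2} with NaN missing."""

    individual_ids: np.ndarray
    snp_ids: np.ndarray
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.individual_ids) or m != len(self.snp_ids):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.snp_ids)} SNPs"
            )
        observed = self.dosages[~np.isnan(self.dosages)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValidationError("non-missing dosages must be 0, 1 or 2")
        if len(set(self.snp_ids)) != m:
            raise ValidationError("snp_ids must be unique")
        if len(set(self.individual_ids)) != n:
            raise ValidationError("individual_ids must be unique")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def column(self, snp_id: str) -> np.ndarray:
        j = self._snp_index(snp_id)
        return self.dosages[:, j]

    def _snp_index(self, snp_id: str) -> int:
        idx = np.flatnonzero(self.snp_ids == snp_id)
        if idx.size == 0:
            raise KeyError(f"SNP {snp_id} not in genotype matrix")
        return int(idx[0])

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        cols = [self._snp_index(s) for s in snp_ids]
        return GenotypeMatrix(
            self.individual_ids.copy(),
            np.asarray(list(snp_ids), dtype=object),
            self.dosages[:, cols].copy(),
        )

    def subset_individuals(self, mask_or_ids) -> "GenotypeMatrix":
        mask = np.asarray(mask_or_ids)
        if mask.dtype != bool:
            wanted = set(mask.tolist())
            mask = np.array([i in wanted for i in self.individual_ids])
        return GenotypeMatrix(
            self.individual_ids[mask].copy(),
            self.snp_ids.copy(),
            self.dosages[mask].copy(),
        )

    def risk_allele_frequency(self, snp_id: str) -> float:
        """Observed risk-allele frequency; missing excluded from denominator."""
        x = self.column(snp_id)
        obs = x[~np.isnan(x)]
        if obs.size == 0:
            return float("nan")
        return float(obs.mean() / 2.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=self.individual_ids, columns=self.snp_ids
        )


@dataclass
class CohortLabels:
    """Per-individual diagnostic group, antibody flags, subpopulation, batch.

    Backed by a DataFrame indexed by individual id with columns
    ``group`` (CONTROL/T1D/T2D/LADA), ``gada``/``ia2a`` (bool, meaningful
    for LADA only), ``subpop`` (int) and ``batch`` (str).
    """

    table: pd.DataFrame = field()

    def __post_init__(self) -> None:
        required = {"group", "gada", "ia2a", "subpop", "batch"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"labels missing columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            raise ValidationError("duplicate individual ids in labels")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")

    @classmethod
    def from_arrays(
        cls,
        individual_ids: Sequence[str],
        group: Sequence[str],
        gada: Sequence[bool] | None = None,
        ia2a: Sequence[bool] | None = None,
        subpop: Sequence[int] | None = None,
        batch: Sequence[str] | None = None,
    ) -> "CohortLabels":
        n = len(individual_ids)
        tbl = pd.DataFrame(
            {
                "group": list(group),
                "gada": list(gada) if gada is not None else [False] * n,
                "ia2a": list(ia2a) if ia2a is not None else [False] * n,
                "subpop": list(subpop) if subpop is not None else [0] * n,
                "batch": list(batch) if batch is not None else ["batch0"] * n,
            },
            index=pd.Index(individual_ids, name="individual_id"),
        )
        return cls(tbl)

    def __len__(self) -> int:
        return len(self.table)

    def aligned_to(self, individual_ids: Sequence[str]) -> pd.DataFrame:
        return self.table.loc[list(individual_ids)]

    def group_mask(self, group: str, individual_ids: Sequence[str]) -> np.ndarray:
        return (self.aligned_to(individual_ids)["group"] == group).to_numpy()

    def subset_mask(self, subset: str, individual_ids: Sequence[str]) -> np.ndarray:
        """Boolean mask for a LADA antibody subset (or ALL_LADA)."""
        tbl = self.aligned_to(individual_ids)
        lada = (tbl["group"] == "LADA").to_numpy()
        if subset == "ALL_LADA":
            return lada
        if subset == "GADA_ONLY":
            return lada & tbl["gada"].to_numpy() & ~tbl["ia2a"].to_numpy()
        if subset == "GADA_IA2A":
            return lada & tbl["gada"].to_numpy() & tbl["ia2a"].to_numpy()
        raise ValidationError(f"unknown case subset {subset!r}")

    def counts(self) -> Mapping[str, int]:
        return self.table["group"].value_counts().to_dict()
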