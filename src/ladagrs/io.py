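"""Readers and writers for manifests, genotypes and result tables.

Formats: tab-separated locus manifest, dosage TSV (individuals x SNPs,
``NA`` for missing), VCF with GT fields (read via cyvcf2).  Coordinates
are 1-based.  Genotypes are always oriented to the manifest risk allele
on read, so downstream code only ever sees risk-allele dosages.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    CohortLabels,
    GenotypeMatrix,
    LocusManifest,
    LocusRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = [
    "snp_id",
    "chromosome",
    "position",
    "risk_allele",
    "other_allele",
    "disease_panel",
    "published_or",
    "hla_role",
]

SCAN_COLUMNS = [
    "snp_id",
    "panel",
    "group_a",
    "group_b",
    "freq_a",
    "freq_b",
    "beta",
    "se",
    "mu",
    "chi2",
    "p",
    "or_approx",
    "significant",
]


class OrientationError(ValidationError):
    """Alleles in the genotype source match neither manifest orientation."""


def read_manifest(path: str | Path, reorient: bool = True) -> LocusManifest:
    """Read a tab-separated locus manifest.

    Absent published ORs are encoded as the literal ``NA``.  With
    ``reorient`` (default), records whose published OR is < 1 are flipped
    (alleles swapped, OR inverted) so every weight counts risk-increasing
    alleles.  Strand-ambiguous (A/T, C/G) loci are logged and taken at
    face value.
    """
    records: list[LocusRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != MANIFEST_COLUMNS:
            raise ValidationError(
                f"manifest header must be {MANIFEST_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(MANIFEST_COLUMNS):
                raise ValidationError(f"line {lineno}: expected 8 fields")
            (snp_id, chrom, pos, risk, other, panel, or_str, hla) = fields
            if snp_id in seen:
                raise ValidationError(f"duplicate snp_id {snp_id} at line {lineno}")
            seen.add(snp_id)
            try:
                rec = LocusRecord(
                    snp_id=snp_id,
                    chromosome=chrom,
                    position=int(pos),
                    risk_allele=risk,
                    other_allele=other,
                    disease_panel=panel,
                    published_or=None if or_str == "NA" else float(or_str),
                    hla_role=hla,
                )
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"line {lineno}: {exc}") from exc
            if rec.is_strand_ambiguous:
                logger.warning(
                    "%s is strand-ambiguous (%s/%s); taken at face value",
                    rec.snp_id,
                    rec.risk_allele,
                    rec.other_allele,
                )
            if reorient and rec.published_or is not None and rec.published_or < 1.0:
                rec = rec.flipped()
            records.append(rec)
    return LocusManifest(records)


def write_manifest(manifest: LocusManifest, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(MANIFEST_COLUMNS) + "\n")
        for r in manifest:
            or_str = "NA" if r.published_or is None else repr(r.published_or)
            fh.write(
                f"{r.snp_id}\t{r.chromosome}\t{r.position}\t{r.risk_allele}\t"
                f"{r.other_allele}\t{r.disease_panel}\t{or_str}\t{r.hla_role}\n"
            )


def orient_to_risk_allele(
    alt_dosage: float, ref: str, alt: str, record: LocusRecord
) -> float:
    """Convert an ALT-allele dosage to a risk-allele dosage.

    Returns ``alt_dosage`` unchanged when ALT is the risk allele, the
    flipped count ``2 - alt_dosage`` when REF is, and propagates missing
    (NaN).  Applying the flip twice is the identity.
    """
    if isinstance(alt_dosage, float) and math.isnan(alt_dosage):
        return alt_dosage
    if alt == record.risk_allele and ref == record.other_allele:
        return alt_dosage
    if ref == record.risk_allele and alt == record.other_allele:
        return 2 - alt_dosage
    raise OrientationError(
        f"{record.snp_id}: VCF alleles {ref}/{alt} match neither orientation of "
        f"{record.risk_allele}/{record.other_allele}"
    )


def read_genotypes(
    path: str | Path, format: str, manifest: LocusManifest
) -> GenotypeMatrix:
    """Read genotypes from a VCF or dosage TSV, oriented to risk alleles.

    Manifest SNPs absent from the file are dropped with a warning.
    """
    if format == "VCF":
        return _read_vcf(path, manifest)
    if format == "dosage-TSV":
        return _read_dosage_tsv(path, manifest)
    raise ValidationError(f"unknown genotype format {format!r}")


def _read_vcf(path: str | Path, manifest: LocusManifest) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    individuals = np.asarray(vcf.samples, dtype=object)
    cols: dict[str, np.ndarray] = {}
    for variant in vcf:
        snp_id = variant.ID
        if snp_id is None or snp_id not in manifest:
            continue
        record = manifest[snp_id]
        if len(variant.ALT) != 1:
            raise ValidationError(f"{snp_id}: only biallelic records supported")
        # gts012: 0/1/2 = ALT count, 3 = missing
        alt_dosage = variant.gt_types.astype(float)
        alt_dosage[alt_dosage == 3] = np.nan
        cols[snp_id] = np.array(
            [
                orient_to_risk_allele(d, variant.REF, variant.ALT[0], record)
                for d in alt_dosage
            ]
        )
    return _assemble(individuals, manifest, cols)


def _read_dosage_tsv(path: str | Path, manifest: LocusManifest) -> GenotypeMatrix:
    tbl = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    individuals = np.asarray(tbl.index.astype(str), dtype=object)
    cols = {s: tbl[s].to_numpy(dtype=float) for s in tbl.columns if s in manifest}
    return _assemble(individuals, manifest, cols)


def _assemble(
    individuals: np.ndarray, manifest: LocusManifest, cols: dict[str, np.ndarray]
) -> GenotypeMatrix:
    kept = [s for s in manifest.snp_ids if s in cols]
    dropped = [s for s in manifest.snp_ids if s not in cols]
    if dropped:
        logger.warning("%d manifest SNP(s) absent from genotype file: %s",
                       len(dropped), ", ".join(dropped))
    dosages = (
        np.column_stack([cols[s] for s in kept])
        if kept
        else np.empty((len(individuals), 0))
    )
    return GenotypeMatrix(individuals, np.asarray(kept, dtype=object), dosages)


def write_dosage_tsv(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a genotype matrix as dosage TSV (``NA`` for missing)."""
    frame = G.to_frame()
    frame.index.name = "individual_id"
    frame.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


def write_labels(labels: CohortLabels, path: str | Path) -> None:
    labels.table.to_csv(path, sep="\t")


def read_labels(path: str | Path) -> CohortLabels:
    tbl = pd.read_csv(path, sep="\t", index_col=0)
    tbl.index = tbl.index.astype(str)
    tbl["gada"] = tbl["gada"].astype(bool)
    tbl["ia2a"] = tbl["ia2a"].astype(bool)
    tbl["batch"] = tbl["batch"].astype(str)
    return CohortLabels(tbl)


def write_scan_results(records: Sequence, path: str | Path) -> None:
    """Write association records as TSV with the documented column order."""
    rows = []
    for r in records:
        rows.append({c: getattr(r, _SCAN_ATTR.get(c, c)) for c in SCAN_COLUMNS})
    pd.DataFrame(rows, columns=SCAN_COLUMNS).to_csv(
        path, sep="\t", index=False, na_rep="NA"
    )


_SCAN_ATTR = {"chi2": "wald_chi2", "freq_a": "freq_a", "freq_b": "freq_b"}


def write_scores(score_frame: pd.DataFrame, path: str | Path) -> None:
    """Write per-individual scores (individual_id, group, gada, ia2a,
    score_type, score)."""
    score_frame.to_csv(path, sep="\t", index=False)
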