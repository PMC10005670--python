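"""Reading and writing genotype and phenotype data.

Supported formats: PLINK text ``.ped``/``.map`` pairs (whitespace
separated, ``0`` = missing allele), VCF v4.2 with GT calls (read through
cyvcf2), a phenotype TSV with header
``subject_id age sex bmi tg_baseline tg_post [response]``, and a variant
annotation TSV fixing each SNP's major/minor allele orientation.

Dosage orientation: when an annotation table is supplied its minor
allele wins, so that a small sample whose empirical frequency crosses
0.5 keeps the published orientation; otherwise the minor allele is the
empirically rarer one (ties break to the lexicographically later
allele).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    VALID_ALLELES,
    Cohort,
    GenotypeMatrix,
    Sex,
    SubjectRecord,
    VariantRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "SchemaError",
    "read_plink_text",
    "write_plink_text",
    "read_vcf",
    "write_vcf",
    "read_phenotypes",
    "write_phenotypes",
    "read_annotation",
    "write_annotation",
    "attach_phenotypes",
]

PHENOTYPE_COLUMNS = ["subject_id", "age", "sex", "bmi", "tg_baseline", "tg_post"]
ANNOTATION_COLUMNS = ["variant_id", "chromosome", "position", "major_allele", "minor_allele"]


class ParseError(ValueError):
    """Malformed genotype file content (message names the offending line)."""


class SchemaError(ValueError):
    """A table is missing required columns."""


# ---------------------------------------------------------------------------
# allele orientation helpers

def _empirical_minor(allele_pairs: Sequence[tuple]) -> tuple:
    """Return (major, minor) from observed allele pairs, missing excluded."""
    counts: dict = {}
    for a, b in allele_pairs:
        for allele in (a, b):
            if allele != "0":
                counts[allele] = counts.get(allele, 0) + 1
    if not counts:
        raise ParseError("variant has no called alleles; cannot orient")
    if len(counts) == 1:
        # monomorphic: observed allele is major; minor unknown -> placeholder
        (only,) = counts
        minor = next(a for a in "ACGT" if a != only)
        return only, minor
    if len(counts) > 2:
        raise ParseError(f"more than two alleles observed: {sorted(counts)}")
    alleles = sorted(counts, key=lambda a: (counts[a], a))
    return alleles[1], alleles[0]


def _annotation_orientation(annotation: pd.DataFrame | None):
    if annotation is None:
        return {}
    frame = annotation.reset_index() if annotation.index.name == "variant_id" else annotation
    missing = {"variant_id", "major_allele", "minor_allele"} - set(frame.columns)
    if missing:
        raise SchemaError(f"annotation table missing columns: {sorted(missing)}")
    return {
        str(row.variant_id): (str(row.major_allele).upper(), str(row.minor_allele).upper())
        for row in frame.itertuples()
    }


def _dosage_from_pairs(pairs, minor: str) -> np.ndarray:
    out = np.empty(len(pairs), dtype=float)
    for i, (a, b) in enumerate(pairs):
        if a == "0" or b == "0":
            out[i] = np.nan
        else:
            out[i] = (a == minor) + (b == minor)
    return out


# ---------------------------------------------------------------------------
# PLINK text

def read_plink_text(
    ped_path, map_path, annotation: pd.DataFrame | None = None
) -> Cohort:
    """Read a PLINK text ``.ped``/``.map`` pair into a :class:`Cohort`.

    The ``.ped`` file must have the six mandatory leading columns
    (FID IID PAT MAT SEX PHENO) followed by two allele columns per
    variant; ``0 0`` allele pairs become missing.  Subject ids are taken
    from the IID column.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    variants_meta = []
    for lineno, line in enumerate(map_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 4:
            raise ParseError(f"{map_path}:{lineno}: expected 4 columns, got {len(fields)}")
        chrom, vid, _cm, pos = fields
        variants_meta.append((chrom, vid, int(pos)))

    n_variants = len(variants_meta)
    subject_ids, sexes, all_pairs = [], [], []
    for lineno, line in enumerate(ped_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        expected = 6 + 2 * n_variants
        if len(fields) != expected:
            raise ParseError(
                f"{ped_path}:{lineno}: expected {expected} columns "
                f"(6 + 2 x {n_variants} variants), got {len(fields)}"
            )
        iid, sex_code = fields[1], fields[4]
        pairs = []
        for j in range(n_variants):
            a, b = fields[6 + 2 * j].upper(), fields[7 + 2 * j].upper()
            for allele in (a, b):
                if allele not in VALID_ALLELES and allele != "0":
                    raise ParseError(
                        f"{ped_path}:{lineno}: invalid allele {allele!r} at variant "
                        f"{variants_meta[j][1]}"
                    )
            pairs.append((a, b))
        subject_ids.append(iid)
        sexes.append({"1": Sex.male, "2": Sex.female}.get(sex_code))
        all_pairs.append(pairs)

    orientation = _annotation_orientation(annotation)
    variant_records, columns = [], []
    for j, (chrom, vid, pos) in enumerate(variants_meta):
        pairs_j = [row[j] for row in all_pairs]
        if vid in orientation:
            major, minor = orientation[vid]
        else:
            major, minor = _empirical_minor(pairs_j)
        variant_records.append(
            VariantRecord(vid, chrom, pos, major_allele=major, minor_allele=minor)
        )
        columns.append(_dosage_from_pairs(pairs_j, minor))

    dosage = np.column_stack(columns) if columns else np.empty((len(subject_ids), 0))
    subjects = [SubjectRecord(sid, sex=sex) for sid, sex in zip(subject_ids, sexes)]
    matrix = GenotypeMatrix(subject_ids, [v.variant_id for v in variant_records], dosage)
    return Cohort(subjects, variant_records, matrix)


def write_plink_text(cohort: Cohort, ped_path, map_path) -> None:
    """Write a cohort's genotypes as a PLINK text pair (inverse of reading)."""
    ped_path, map_path = Path(ped_path), Path(map_path)
    with map_path.open("w") as fh:
        for v in cohort.variants:
            fh.write(f"{v.chromosome}\t{v.variant_id}\t0\t{v.position}\n")
    sex_code = {Sex.male: "1", Sex.female: "2", None: "0"}
    vmap = cohort.variant_map
    with ped_path.open("w") as fh:
        for subject in cohort.subjects:
            row = cohort.genotypes.row(subject.subject_id)
            fields = [
                subject.subject_id,
                subject.subject_id,
                "0",
                "0",
                sex_code[subject.sex],
                "-9",
            ]
            for v, d in zip(cohort.variants, row):
                rec = vmap[v.variant_id]
                if np.isnan(d):
                    fields += ["0", "0"]
                else:
                    n_minor = int(d)
                    fields += [rec.minor_allele] * n_minor + [rec.major_allele] * (2 - n_minor)
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# VCF

def read_vcf(vcf_path, annotation: pd.DataFrame | None = None) -> Cohort:
    """Read a VCF (v4.2, GT field, diploid, biallelic) into a :class:`Cohort`.

    Dosage is the ALT-allele count when ALT is the minor allele; when the
    annotation says ALT is the major allele the count is flipped
    (``2 - count``) with a logged warning.  ``./.`` becomes missing.
    """
    from cyvcf2 import VCF

    orientation = _annotation_orientation(annotation)
    vcf = VCF(str(vcf_path))
    subject_ids = list(vcf.samples)
    variant_records, columns = [], []
    for record in vcf:
        if len(record.ALT) != 1:
            raise ParseError(
                f"{vcf_path}: multi-allelic site {record.ID or record.POS}; "
                "split multi-allelic records before reading"
            )
        ref, alt = record.REF.upper(), record.ALT[0].upper()
        vid = record.ID or f"{record.CHROM}:{record.POS}"
        alt_counts = np.empty(len(subject_ids), dtype=float)
        for i, gt in enumerate(record.genotypes):
            alleles = [a for a in gt[:-1]]
            if any(a < 0 for a in alleles):
                alt_counts[i] = np.nan
            else:
                alt_counts[i] = sum(a == 1 for a in alleles)
        if vid in orientation:
            major, minor = orientation[vid]
            if {ref, alt} != {major, minor}:
                raise ParseError(
                    f"{vcf_path}: {vid} alleles {ref}/{alt} do not match annotation "
                    f"{major}/{minor}"
                )
            flip = alt == major
        else:
            called = alt_counts[~np.isnan(alt_counts)]
            if called.size == 0:
                raise ParseError(f"{vcf_path}: {vid} has no called genotypes")
            flip = called.mean() / 2.0 > 0.5
            major, minor = (alt, ref) if flip else (ref, alt)
        if flip:
            logger.warning("%s: ALT %s is the major allele; flipping dosage", vid, alt)
            dosage = 2.0 - alt_counts
        else:
            dosage = alt_counts
        variant_records.append(
            VariantRecord(vid, record.CHROM, record.POS, major_allele=major, minor_allele=minor)
        )
        columns.append(dosage)

    dosage = np.column_stack(columns) if columns else np.empty((len(subject_ids), 0))
    subjects = [SubjectRecord(sid) for sid in subject_ids]
    matrix = GenotypeMatrix(subject_ids, [v.variant_id for v in variant_records], dosage)
    return Cohort(subjects, variant_records, matrix)


def write_vcf(cohort: Cohort, vcf_path, ref_is_major: bool = True) -> None:
    """Write genotypes as an uncompressed VCF v4.2 text file.

    With ``ref_is_major`` (default) REF is the major allele so that the
    ALT count equals the minor-allele dosage; the opposite setting writes
    a swapped-orientation file (useful for flip-symmetry checks).
    """
    vcf_path = Path(vcf_path)
    ids = cohort.genotypes.subjects
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids),
    ]
    # cohort order is preserved (not coordinate-sorted) so that a
    # write-then-read round trip reproduces the dosage matrix exactly
    for v in cohort.variants:
        column = cohort.genotypes.column(v.variant_id)
        ref, alt = (v.major_allele, v.minor_allele) if ref_is_major else (
            v.minor_allele,
            v.major_allele,
        )
        gts = []
        for d in column:
            if np.isnan(d):
                gts.append("./.")
            else:
                n_alt = int(d) if ref_is_major else 2 - int(d)
                gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[n_alt])
        lines.append(
            f"{v.chromosome}\t{v.position}\t{v.variant_id}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
            + "\t".join(gts)
        )
    vcf_path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# phenotype and annotation tables

def read_phenotypes(tsv_path) -> list:
    """Read the phenotype TSV into a list of :class:`SubjectRecord`.

    Required columns: ``subject_id age sex bmi tg_baseline tg_post``; an
    optional ``response`` column carries pre-filled labels through
    unchanged.  Unknown extra columns are preserved in ``record.extra``.
    """
    frame = pd.read_csv(tsv_path, sep="\t", dtype={"subject_id": str})
    missing = set(PHENOTYPE_COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"phenotype table missing required columns: {sorted(missing)}")
    extra_cols = [c for c in frame.columns if c not in PHENOTYPE_COLUMNS + ["response"]]
    records = []
    for row in frame.itertuples(index=False):
        data = row._asdict()
        records.append(
            SubjectRecord(
                subject_id=data["subject_id"],
                age=data["age"],
                sex=None if pd.isna(data["sex"]) else data["sex"],
                bmi=data["bmi"],
                tg_baseline=data["tg_baseline"],
                tg_post=data["tg_post"],
                response_label=data.get("response"),
                extra={c: data[c] for c in extra_cols},
            )
        )
    return records


def write_phenotypes(subjects: Iterable[SubjectRecord], tsv_path) -> None:
    rows = []
    for s in subjects:
        rows.append(
            {
                "subject_id": s.subject_id,
                "age": s.age,
                "sex": s.sex.value if s.sex else "",
                "bmi": s.bmi,
                "tg_baseline": s.tg_baseline,
                "tg_post": s.tg_post,
                "response": s.response_label.value,
                **s.extra,
            }
        )
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")


def read_annotation(tsv_path) -> pd.DataFrame:
    """Read the variant annotation TSV (allele orientation + location)."""
    frame = pd.read_csv(tsv_path, sep="\t", dtype={"variant_id": str, "chromosome": str})
    missing = set(ANNOTATION_COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"annotation table missing required columns: {sorted(missing)}")
    return frame


def write_annotation(variants: Iterable[VariantRecord], tsv_path) -> None:
    rows = [
        {
            "variant_id": v.variant_id,
            "chromosome": v.chromosome,
            "position": v.position,
            "major_allele": v.major_allele,
            "minor_allele": v.minor_allele,
            "nearest_gene": v.nearest_gene,
            "phenotype": ".".join(sorted(v.phenotypes)) if v.phenotypes else "",
        }
        for v in variants
    ]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


def annotation_records(frame: pd.DataFrame) -> list:
    """Convert an annotation frame to :class:`VariantRecord` objects."""
    records = []
    for row in frame.itertuples(index=False):
        data = row._asdict()
        phenotypes = frozenset(
            p for p in str(data.get("phenotype", "") or "").split(".") if p and p != "nan"
        )
        records.append(
            VariantRecord(
                variant_id=data["variant_id"],
                chromosome=str(data["chromosome"]),
                position=int(data["position"]),
                major_allele=data["major_allele"],
                minor_allele=data["minor_allele"],
                nearest_gene=str(data.get("nearest_gene", "") or ""),
                phenotypes=phenotypes,
            )
        )
    return records


def attach_phenotypes(cohort: Cohort, records: Iterable[SubjectRecord]) -> Cohort:
    """Merge phenotype records into a genotype-derived cohort by subject id."""
    genotype_sex = {s.subject_id: s.sex for s in cohort.subjects}
    merged = []
    for record in records:
        if record.sex is None and genotype_sex.get(record.subject_id) is not None:
            record = SubjectRecord(**{**record.__dict__, "sex": genotype_sex[record.subject_id]})
        merged.append(record)
    return cohort.with_subject_records(merged)
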