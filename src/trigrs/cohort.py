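"""Cohort containers for fish-oil triglyceride-response genetics.

Subjects are participants of a six-week fish-oil (n-3 fatty acid)
supplementation trial with plasma triglycerides (TG, mmol/L) measured
before and after supplementation; variants are SNPs genotyped on those
subjects and stored as minor-allele dosages (0/1/2 copies, NaN missing).

A subject is a *responder* when their plasma TG decreased over the
intervention (change <= -0.01 mmol/L), a *nonresponder* when TG stayed
stable or increased (change >= 0.00 mmol/L), and *unclassified* in the
sliver between the two bounds.  "Extreme" responders additionally show
at least a 10% relative TG decrease.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Sex",
    "ResponseLabel",
    "Classification",
    "ClassificationError",
    "SubjectRecord",
    "VariantRecord",
    "GenotypeMatrix",
    "Cohort",
    "classify_response",
    "RESPONDER_MAX_CHANGE",
    "NONRESPONDER_MIN_CHANGE",
    "EXTREME_FRACTION",
]

#: TG change (post - baseline, mmol/L) at or below which a subject is a responder.
RESPONDER_MAX_CHANGE = -0.01
#: TG change at or above which a subject is a nonresponder.
NONRESPONDER_MIN_CHANGE = 0.0
#: Relative TG decrease qualifying a responder as "extreme".
EXTREME_FRACTION = 0.10

VALID_ALLELES = frozenset("ACGT")


class Sex(str, Enum):
    female = "female"
    male = "male"


class ResponseLabel(str, Enum):
    responder = "responder"
    nonresponder = "nonresponder"
    unclassified = "unclassified"


class ClassificationError(ValueError):
    """Raised when a subject cannot be classified (missing TG values)."""


class Classification(NamedTuple):
    label: ResponseLabel
    extreme: bool
    tg_change: float


def classify_response(
    subject,
    extreme_fraction: float = EXTREME_FRACTION,
    responder_bound: float = RESPONDER_MAX_CHANGE,
    nonresponder_bound: float = NONRESPONDER_MIN_CHANGE,
) -> Classification:
    """Classify a subject's TG response to the supplementation.

    Parameters
    ----------
    subject
        A :class:`SubjectRecord`, or a ``(tg_baseline, tg_post)`` pair in
        mmol/L.
    extreme_fraction
        Minimum relative decrease for the extreme-responder flag
        (default 10%).
    responder_bound, nonresponder_bound
        The two classification bounds on the TG change.  Defaults follow
        the study rule: responder iff change <= -0.01, nonresponder iff
        change >= 0.00; the open interval in between is unclassified.

    Returns
    -------
    Classification
        ``(label, extreme, tg_change)``.
    """
    if isinstance(subject, SubjectRecord):
        baseline, post = subject.tg_baseline, subject.tg_post
    else:
        baseline, post = subject
    if baseline is None or post is None or np.isnan(baseline) or np.isnan(post):
        raise ClassificationError("both baseline and post TG values are required")
    change = post - baseline
    if change <= responder_bound:
        # tiny absolute slack so an exact 10% decrease is not lost to
        # floating-point rounding of the relative change
        extreme = (baseline - post) >= extreme_fraction * baseline - 1e-9
        return Classification(ResponseLabel.responder, extreme, change)
    if change >= nonresponder_bound:
        return Classification(ResponseLabel.nonresponder, False, change)
    return Classification(ResponseLabel.unclassified, False, change)


def _coerce_sex(value):
    if value is None or isinstance(value, Sex):
        return value
    if isinstance(value, str):
        return Sex(value.lower())
    raise ValueError(f"cannot interpret sex value {value!r}")


def _coerce_label(value):
    if value is None:
        return ResponseLabel.unclassified
    if isinstance(value, ResponseLabel):
        return value
    return ResponseLabel(str(value).lower())


@dataclass
class SubjectRecord:
    """One participant: identifiers, clinical covariates and TG measurements.

    ``age`` in years, ``bmi`` in kg/m2, TG values in mmol/L.  Fields other
    than ``subject_id`` may be ``None`` when unknown (e.g. a genotype file
    read before phenotypes are attached).  ``extra`` preserves unknown
    phenotype-table columns untouched.
    """

    subject_id: str
    age: float | None = None
    sex: Sex | None = None
    bmi: float | None = None
    tg_baseline: float | None = None
    tg_post: float | None = None
    response_label: ResponseLabel = ResponseLabel.unclassified
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.subject_id = str(self.subject_id)
        self.sex = _coerce_sex(self.sex)
        self.response_label = _coerce_label(self.response_label)
        for name in ("age", "bmi", "tg_baseline", "tg_post"):
            value = getattr(self, name)
            if value is not None:
                value = float(value)
                if np.isnan(value):
                    value = None
                elif value <= 0:
                    raise ValueError(
                        f"{name} must be positive for subject {self.subject_id}, got {value}"
                    )
                setattr(self, name, value)

    def classify(self, extreme_fraction: float = EXTREME_FRACTION) -> Classification:
        return classify_response(self, extreme_fraction=extreme_fraction)

    def with_label(self, label: ResponseLabel) -> "SubjectRecord":
        return dataclasses.replace(self, response_label=_coerce_label(label))


@dataclass(frozen=True)
class VariantRecord:
    """Annotation for one SNP: genomic location, allele orientation, gene.

    ``phenotypes`` holds the lipid traits the variant was reported to
    interact with (subset of TG / LDL / HDL / TC); purely informational.
    """

    variant_id: str
    chromosome: str
    position: int
    major_allele: str
    minor_allele: str
    nearest_gene: str = ""
    phenotypes: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "major_allele", self.major_allele.upper())
        object.__setattr__(self, "minor_allele", self.minor_allele.upper())
        object.__setattr__(self, "phenotypes", frozenset(self.phenotypes))
        if self.major_allele == self.minor_allele:
            raise ValueError(f"{self.variant_id}: major and minor allele are identical")
        for allele in (self.major_allele, self.minor_allele):
            if allele not in VALID_ALLELES:
                raise ValueError(f"{self.variant_id}: invalid allele {allele!r}")
        if int(self.position) < 1:
            raise ValueError(f"{self.variant_id}: position must be >= 1 (1-based)")
        object.__setattr__(self, "position", int(self.position))


class GenotypeMatrix:
    """Subjects x variants minor-allele dosage matrix.

    Entries are 0, 1 or 2 minor-allele copies; missing genotypes are NaN.
    """

    def __init__(self, subjects: Sequence[str], variants: Sequence[str], dosage):
        self.subjects = [str(s) for s in subjects]
        self.variants = [str(v) for v in variants]
        dosage = np.array(dosage, dtype=float)
        if dosage.shape != (len(self.subjects), len(self.variants)):
            raise ValueError(
                f"dosage shape {dosage.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.variants)} variants"
            )
        if len(set(self.subjects)) != len(self.subjects):
            raise ValueError("duplicate subject ids in genotype matrix")
        if len(set(self.variants)) != len(self.variants):
            raise ValueError("duplicate variant ids in genotype matrix")
        valid = np.isnan(dosage) | np.isin(dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = dosage[~valid][0]
            raise ValueError(f"dosage entries must be 0, 1, 2 or missing; found {bad}")
        self.dosage = dosage
        self._subject_index = {s: i for i, s in enumerate(self.subjects)}
        self._variant_index = {v: j for j, v in enumerate(self.variants)}

    @property
    def shape(self):
        return self.dosage.shape

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosage[:, self._variant_index[variant_id]]

    def row(self, subject_id: str) -> np.ndarray:
        return self.dosage[self._subject_index[subject_id]]

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.subjects, columns=self.variants)

    def subset(
        self,
        subject_ids: Iterable[str] | None = None,
        variant_ids: Iterable[str] | None = None,
    ) -> "GenotypeMatrix":
        subject_ids = self.subjects if subject_ids is None else list(subject_ids)
        variant_ids = self.variants if variant_ids is None else list(variant_ids)
        rows = [self._subject_index[s] for s in subject_ids]
        cols = [self._variant_index[v] for v in variant_ids]
        return GenotypeMatrix(subject_ids, variant_ids, self.dosage[np.ix_(rows, cols)])

    def __eq__(self, other):
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.subjects == other.subjects
            and self.variants == other.variants
            and np.array_equal(self.dosage, other.dosage, equal_nan=True)
        )


@dataclass
class Cohort:
    """A study cohort: subject records, variant annotations and genotypes."""

    subjects: list
    variants: list
    genotypes: GenotypeMatrix

    def __post_init__(self):
        subject_ids = {s.subject_id for s in self.subjects}
        variant_ids = {v.variant_id for v in self.variants}
        if len(subject_ids) != len(self.subjects):
            raise ValueError("duplicate subject ids in cohort")
        if len(variant_ids) != len(self.variants):
            raise ValueError("duplicate variant ids in cohort")
        missing_s = set(self.genotypes.subjects) - subject_ids
        missing_v = set(self.genotypes.variants) - variant_ids
        if missing_s:
            raise ValueError(f"genotype subjects not in cohort: {sorted(missing_s)[:5]}")
        if missing_v:
            raise ValueError(f"genotype variants not in cohort: {sorted(missing_v)[:5]}")

    @property
    def subject_map(self) -> Mapping[str, SubjectRecord]:
        return {s.subject_id: s for s in self.subjects}

    @property
    def variant_map(self) -> Mapping[str, VariantRecord]:
        return {v.variant_id: v for v in self.variants}

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def labels(self) -> pd.Series:
        """Response labels indexed by subject id (genotype row order)."""
        records = self.subject_map
        return pd.Series(
            {sid: records[sid].response_label.value for sid in self.genotypes.subjects},
            name="response",
        ).reindex(self.genotypes.subjects)

    def labelled_ids(self, label: ResponseLabel | str | None = None) -> list:
        """Subject ids with a definite response label (optionally one label)."""
        if label is not None:
            label = ResponseLabel(label)
            return [
                s.subject_id for s in self.subjects if s.response_label == label
            ]
        return [
            s.subject_id
            for s in self.subjects
            if s.response_label != ResponseLabel.unclassified
        ]

    def phenotype_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "age": s.age,
                    "sex": s.sex.value if s.sex is not None else None,
                    "bmi": s.bmi,
                    "tg_baseline": s.tg_baseline,
                    "tg_post": s.tg_post,
                    "response": s.response_label.value,
                }
            )
        return pd.DataFrame(rows).set_index("subject_id")

    def with_subject_records(self, records: Iterable[SubjectRecord]) -> "Cohort":
        """Replace subject records (e.g. attach phenotypes to genotype ids)."""
        by_id = {r.subject_id: r for r in records}
        unknown = set(by_id) - {s.subject_id for s in self.subjects}
        if unknown:
            raise ValueError(f"phenotype records for unknown subjects: {sorted(unknown)[:5]}")
        merged = [by_id.get(s.subject_id, s) for s in self.subjects]
        return Cohort(merged, self.variants, self.genotypes)

    def derive_labels(self, extreme_fraction: float = EXTREME_FRACTION) -> "Cohort":
        """Fill response labels from the TG classification rule where possible."""
        updated = []
        for s in self.subjects:
            if s.tg_baseline is not None and s.tg_post is not None:
                updated.append(s.with_label(s.classify(extreme_fraction).label))
            else:
                updated.append(s)
        return Cohort(updated, self.variants, self.genotypes)

    def subset(
        self,
        subject_ids: Iterable[str] | None = None,
        variant_ids: Iterable[str] | None = None,
    ) -> "Cohort":
        subject_ids = (
            [s.subject_id for s in self.subjects] if subject_ids is None else list(subject_ids)
        )
        variant_ids = (
            [v.variant_id for v in self.variants] if variant_ids is None else list(variant_ids)
        )
        smap, vmap = self.subject_map, self.variant_map
        return Cohort(
            [smap[s] for s in subject_ids],
            [vmap[v] for v in variant_ids],
            self.genotypes.subset(subject_ids, variant_ids),
        )
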