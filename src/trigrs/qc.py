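"""Per-variant quality control.

Minor-allele frequency (overall and per response group), the exact
conditional Hardy-Weinberg equilibrium test, monomorphic detection, and
the QC filtering policy used before risk-score construction: monomorphic
variants are *excluded* (no participant carries the rare allele), while
variants failing HWE at the chosen alpha are *flagged* but retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist

from .cohort import Cohort, ResponseLabel

__all__ = [
    "AlleleCounts",
    "VariantQC",
    "QCResult",
    "allele_counts",
    "compute_maf",
    "hwe_exact_test",
    "hwe_chi2_test",
    "compute_variant_qc",
    "qc_filter",
]


class AlleleCounts(NamedTuple):
    minor_count: int
    total_alleles: int
    genotype_counts: tuple  # (hom_major, het, hom_minor)


@dataclass
class VariantQC:
    variant_id: str
    maf_all: float
    maf_responders: float
    maf_nonresponders: float
    hwe_p: float
    monomorphic: bool
    n_called: int
    hwe_flag: bool = False


def allele_counts(dosages) -> AlleleCounts:
    """Tally minor alleles and genotype classes from a dosage vector.

    Missing entries (NaN) are excluded pairwise; an empty or all-missing
    vector returns zeros.
    """
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    hom_major = int(np.sum(d == 0))
    het = int(np.sum(d == 1))
    hom_minor = int(np.sum(d == 2))
    minor = het + 2 * hom_minor
    total = 2 * d.size
    return AlleleCounts(minor, total, (hom_major, het, hom_minor))


def compute_maf(dosages) -> float:
    """Minor-allele frequency: minor allele count over total called alleles."""
    counts = allele_counts(dosages)
    if counts.total_alleles == 0:
        raise ValueError("MAF undefined: all genotypes missing")
    return counts.minor_count / counts.total_alleles


def hwe_exact_test(genotype_counts: Sequence[int], midp: bool = False) -> float:
    """Two-sided exact Hardy-Weinberg equilibrium test.

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote configurations no more probable than the observed
    one (the standard exact formulation; ``midp=True`` halves the
    observed configuration's contribution).

    Parameters
    ----------
    genotype_counts
        ``(hom_major, het, hom_minor)`` non-negative integers.

    Returns
    -------
    float
        p-value in (0, 1].
    """
    hom_major, het, hom_minor = (int(c) for c in genotype_counts)
    if min(hom_major, het, hom_minor) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = hom_major + het + hom_minor
    if n == 0:
        raise ValueError("HWE test undefined for zero subjects")
    minor_copies = 2 * hom_minor + het
    rare = min(minor_copies, 2 * n - minor_copies)
    if rare == 0:
        return 1.0  # only one configuration exists when one allele is absent

    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    # P(het | n, rare) proportional to 2^het * n! / (hom_rare! het! hom_common!)
    logw = (
        hets * np.log(2.0)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
    )
    logw -= logw.max()
    probs = np.exp(logw)
    probs /= probs.sum()
    p_obs = probs[hets == het][0]
    mask = probs <= p_obs * (1 + 1e-12)
    p = probs[mask].sum()
    if midp:
        p -= 0.5 * p_obs
    return float(min(p, 1.0))


def hwe_chi2_test(genotype_counts: Sequence[int]) -> float:
    """Asymptotic one-degree-of-freedom chi-square HWE test (cross-check)."""
    hom_major, het, hom_minor = (int(c) for c in genotype_counts)
    n = hom_major + het + hom_minor
    if n == 0:
        raise ValueError("HWE test undefined for zero subjects")
    q = (2 * hom_minor + het) / (2 * n)
    p = 1 - q
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    if np.any(expected == 0):
        return 1.0
    observed = np.array([hom_major, het, hom_minor], dtype=float)
    stat = float(np.sum((observed - expected) ** 2 / expected))
    return float(chi2_dist.sf(stat, df=1))


def _group_maf(cohort: Cohort, variant_id: str, label: ResponseLabel) -> float:
    ids = cohort.labelled_ids(label)
    if not ids:
        return np.nan
    column = cohort.genotypes.subset(subject_ids=ids).column(variant_id)
    counts = allele_counts(column)
    if counts.total_alleles == 0:
        return np.nan
    return counts.minor_count / counts.total_alleles


def compute_variant_qc(cohort: Cohort, hwe_alpha: float = 0.05) -> list:
    """Per-variant QC statistics over the whole cohort.

    Per-group MAFs use only subjects with a definite response label;
    overall MAF and the HWE test use all called genotypes.
    """
    results = []
    for variant in cohort.variants:
        column = cohort.genotypes.column(variant.variant_id)
        counts = allele_counts(column)
        if counts.total_alleles == 0:
            maf = np.nan
            hwe_p = np.nan
        else:
            maf = counts.minor_count / counts.total_alleles
            hwe_p = hwe_exact_test(counts.genotype_counts)
        monomorphic = counts.total_alleles > 0 and counts.minor_count == 0
        results.append(
            VariantQC(
                variant_id=variant.variant_id,
                maf_all=maf,
                maf_responders=_group_maf(cohort, variant.variant_id, ResponseLabel.responder),
                maf_nonresponders=_group_maf(
                    cohort, variant.variant_id, ResponseLabel.nonresponder
                ),
                hwe_p=hwe_p,
                monomorphic=monomorphic,
                n_called=counts.total_alleles // 2,
                hwe_flag=bool(hwe_p < hwe_alpha) if not np.isnan(hwe_p) else False,
            )
        )
    return results


@dataclass
class QCResult:
    passing: list  # variant ids retained
    excluded: list  # (variant_id, reason) pairs
    flagged: list  # variant ids failing HWE at alpha but retained
    table: pd.DataFrame  # one row per variant with all VariantQC fields

    def report_frame(self) -> pd.DataFrame:
        return self.table


def qc_filter(cohort: Cohort, hwe_alpha: float = 0.05) -> QCResult:
    """Apply the QC policy: drop monomorphic variants, flag HWE failures.

    HWE failure alone never removes a variant; the flag (at
    ``hwe_alpha``, default 0.05) is recorded in the report so downstream
    users can act on it.
    """
    stats = compute_variant_qc(cohort, hwe_alpha=hwe_alpha)
    passing, excluded, flagged, rows = [], [], [], []
    for qc in stats:
        reason = ""
        if qc.monomorphic:
            reason = "monomorphic (MAF = 0)"
            excluded.append((qc.variant_id, reason))
        else:
            passing.append(qc.variant_id)
            if qc.hwe_flag:
                flagged.append(qc.variant_id)
        rows.append(
            {
                "variant_id": qc.variant_id,
                "maf_all": qc.maf_all,
                "maf_responders": qc.maf_responders,
                "maf_nonresponders": qc.maf_nonresponders,
                "hwe_p": qc.hwe_p,
                "monomorphic": qc.monomorphic,
                "hwe_flag": qc.hwe_flag,
                "n_called": qc.n_called,
                "excluded_reason": reason,
            }
        )
    return QCResult(passing, excluded, flagged, pd.DataFrame(rows))
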