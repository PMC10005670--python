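"""Odds-ratio based risk-score construction.

Each SNP's minor-allele frequency is compared between responders and
nonresponders as an allele-level odds ratio.  A score of +1 goes to
SNPs whose minor allele is enriched in nonresponders (OR < 1 with the
responder-over-nonresponder odds orientation) — carrying such "risk"
alleles predicts *failing* to lower plasma TG — and −1 to SNPs enriched
in responders (OR > 1).  SNPs with MAF = 0 among responders (and the
degenerate OR = 1) are excluded from score construction.  A subject's
genetic risk score (GRS) is the dosage-weighted sum of these signed
scores; in the weighted variant each term is additionally scaled by the
magnitude of an externally supplied interaction effect size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import Cohort, ResponseLabel
from .qc import allele_counts

__all__ = [
    "OddsRatio",
    "ScoreEntry",
    "ScoreSet",
    "allele_odds_ratio",
    "assign_score",
    "estimate_scores",
    "compute_grs",
    "grs_profiles",
    "build_score_sets",
    "apply_weights",
]


class OddsRatio(NamedTuple):
    value: float  # may be 0.0 (no minor allele in responders) or inf
    ci_low: float  # NaN when counts unavailable
    ci_high: float


def allele_odds_ratio(
    maf_responders: float,
    maf_nonresponders: float,
    counts: tuple | None = None,
    flip: bool = False,
) -> OddsRatio:
    """Allele-level odds ratio between responders and nonresponders.

    The default orientation is responder odds over nonresponder odds,
    ``[p_R/(1-p_R)] / [p_NR/(1-p_NR)]``, which is the orientation
    consistent with the published score table (minor allele rarer in
    responders => OR < 1 => score +1).  ``flip=True`` returns the
    reciprocal orientation.

    Parameters
    ----------
    counts
        Optional allele counts ``(minor_R, major_R, minor_NR, major_NR)``.
        When given, the OR is the 2x2 cross-product ratio and a 95% CI
        is computed by the log-OR normal (Woolf) approximation; from
        proportions alone the CI is undefined (NaN).

    Returns
    -------
    OddsRatio
        ``value`` is 0.0 when the responder MAF is zero (exclusion
        signal) and ``inf`` when only the nonresponder MAF is zero.
    """
    if counts is not None:
        a, b, c, d = (float(x) for x in counts)  # minor_R, major_R, minor_NR, major_NR
        p_r = a / (a + b) if a + b else np.nan
        p_nr = c / (c + d) if c + d else np.nan
    else:
        p_r, p_nr = float(maf_responders), float(maf_nonresponders)
    for p, name in ((p_r, "responder"), (p_nr, "nonresponder")):
        if not 0 <= p < 1:
            raise ValueError(f"{name} MAF must be in [0, 1), got {p}")

    if p_r == 0:
        value = 0.0
    elif p_nr == 0:
        value = math.inf
    else:
        value = (p_r / (1 - p_r)) / (p_nr / (1 - p_nr))
    if flip and value not in (0.0, math.inf):
        value = 1.0 / value
    elif flip:
        value = math.inf if value == 0.0 else 0.0

    ci_low = ci_high = math.nan
    if counts is not None and min(counts) > 0 and value not in (0.0, math.inf):
        a, b, c, d = counts
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        z = norm.ppf(0.975)
        ci_low = value * math.exp(-z * se)
        ci_high = value * math.exp(z * se)
    return OddsRatio(value, ci_low, ci_high)


def assign_score(odds_ratio: float, maf_responders: float) -> int | None:
    """Assign the +/-1 risk score; ``None`` marks an excluded variant.

    Excluded when the responder-group MAF is zero or the OR is exactly 1;
    otherwise +1 for OR < 1 (minor allele enriched in nonresponders) and
    -1 for OR > 1.
    """
    if maf_responders == 0 or odds_ratio == 1:
        return None
    return 1 if odds_ratio < 1 else -1


@dataclass
class ScoreEntry:
    """Per-variant scoring result: OR, CI, assigned score, optional weight."""

    variant_id: str
    odds_ratio: float
    ci_low: float = math.nan
    ci_high: float = math.nan
    score: int | None = None  # +1 / -1 / None (excluded)
    weight: float = 1.0

    @property
    def excluded(self) -> bool:
        return self.score is None


@dataclass
class ScoreSet:
    """A named panel of scored variants (e.g. GRS32, GRS38, GRS46)."""

    name: str
    entries: list = field(default_factory=list)

    def __post_init__(self):
        ids = [e.variant_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.name}: duplicate variant ids in score set")

    @property
    def scored_entries(self) -> list:
        return [e for e in self.entries if not e.excluded]

    @property
    def variant_ids(self) -> list:
        return [e.variant_id for e in self.entries]

    def score_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variant_id": e.variant_id,
                "odds_ratio": e.odds_ratio,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "score": e.score if e.score is not None else "",
                "weight": e.weight,
            }
            for e in self.entries
        ]
        return pd.DataFrame(rows)


def estimate_scores(
    cohort: Cohort,
    variant_ids: Sequence[str] | None = None,
    subject_ids: Sequence[str] | None = None,
    name: str = "GRS",
    flip: bool = False,
) -> ScoreSet:
    """Estimate per-variant odds ratios and scores from labelled subjects.

    ``subject_ids`` restricts the estimation sample (e.g. a training
    split); only subjects with a definite responder/nonresponder label
    contribute allele counts.
    """
    variant_ids = list(variant_ids) if variant_ids is not None else [
        v.variant_id for v in cohort.variants
    ]
    pool = set(subject_ids) if subject_ids is not None else None
    resp = [s for s in cohort.labelled_ids(ResponseLabel.responder) if pool is None or s in pool]
    nonresp = [
        s for s in cohort.labelled_ids(ResponseLabel.nonresponder) if pool is None or s in pool
    ]
    if not resp or not nonresp:
        raise ValueError("score estimation requires labelled subjects in both groups")
    geno_r = cohort.genotypes.subset(subject_ids=resp)
    geno_nr = cohort.genotypes.subset(subject_ids=nonresp)

    entries = []
    for vid in variant_ids:
        c_r = allele_counts(geno_r.column(vid))
        c_nr = allele_counts(geno_nr.column(vid))
        if c_r.total_alleles == 0 or c_nr.total_alleles == 0:
            entries.append(ScoreEntry(vid, math.nan, score=None))
            continue
        counts = (
            c_r.minor_count,
            c_r.total_alleles - c_r.minor_count,
            c_nr.minor_count,
            c_nr.total_alleles - c_nr.minor_count,
        )
        maf_r = c_r.minor_count / c_r.total_alleles
        orr = allele_odds_ratio(maf_r, c_nr.minor_count / c_nr.total_alleles,
                                counts=counts, flip=flip)
        entries.append(
            ScoreEntry(vid, orr.value, orr.ci_low, orr.ci_high,
                       score=assign_score(orr.value, maf_r))
        )
    return ScoreSet(name, entries)


def compute_grs(
    dosages: Mapping[str, float] | pd.Series,
    score_set: ScoreSet,
    weighted: bool = False,
) -> float:
    """One subject's GRS: sum of score x dosage over non-excluded variants.

    The weighted form scales each term by ``|weight|``.  Missing dosages
    must be resolved (imputed) before calling; see :func:`grs_profiles`.
    """
    if isinstance(dosages, pd.Series):
        dosages = dosages.to_dict()
    total = 0.0
    missing = []
    for entry in score_set.scored_entries:
        if entry.variant_id not in dosages or pd.isna(dosages[entry.variant_id]):
            missing.append(entry.variant_id)
            continue
        factor = abs(entry.weight) if weighted else 1.0
        total += entry.score * factor * dosages[entry.variant_id]
    if missing:
        raise ValueError(f"{score_set.name}: no dosage for scored variants {missing}")
    return total


def grs_profiles(
    cohort: Cohort,
    score_sets: Iterable[ScoreSet],
    weighted: bool = False,
    missing: str = "mean",
) -> pd.DataFrame:
    """Per-subject GRS values, one column per score set.

    Missing dosages at scored variants are handled per ``missing``:
    ``"mean"`` (default) substitutes the cohort mean dosage of that
    variant, ``"zero"`` substitutes 0, ``"drop"`` removes subjects with
    any missing scored dosage.
    """
    score_sets = list(score_sets)
    frame = cohort.genotypes.dosage_frame()
    needed = sorted({vid for ss in score_sets for e in ss.scored_entries for vid in [e.variant_id]})
    absent = [v for v in needed if v not in frame.columns]
    if absent:
        raise ValueError(f"scored variants absent from genotype data: {absent}")
    sub = frame[needed].copy()
    if missing == "mean":
        sub = sub.fillna(sub.mean())
    elif missing == "zero":
        sub = sub.fillna(0.0)
    elif missing == "drop":
        sub = sub.dropna()
    else:
        raise ValueError(f"unknown missing-dosage policy {missing!r}")
    out = {}
    for ss in score_sets:
        vids = [e.variant_id for e in ss.scored_entries]
        signs = np.array([e.score * (abs(e.weight) if weighted else 1.0)
                          for e in ss.scored_entries])
        out[ss.name] = sub[vids].to_numpy() @ signs if vids else np.zeros(len(sub))
    return pd.DataFrame(out, index=sub.index.rename("subject_id"))


def build_score_sets(
    base_set: ScoreSet,
    additions: Sequence[Sequence[ScoreEntry]],
    names: Sequence[str],
) -> list:
    """Build extended score sets, each the base panel plus one addition list.

    ``additions[i]`` is appended to the base to form the set named
    ``names[i]``; a variant occurring both in the base and an addition
    is an error.
    """
    if len(additions) != len(names):
        raise ValueError("one name per addition list is required")
    base_ids = set(base_set.variant_ids)
    sets = []
    for name, extra in zip(names, additions):
        dup = base_ids & {e.variant_id for e in extra}
        if dup:
            raise ValueError(f"{name}: variants duplicated between base and additions: {sorted(dup)}")
        sets.append(ScoreSet(name, list(base_set.entries) + list(extra)))
    return sets


def apply_weights(score_set: ScoreSet, weights: Mapping[str, float]) -> ScoreSet:
    """Return a copy of the score set with per-variant weights attached."""
    entries = [
        replace(e, weight=float(weights.get(e.variant_id, e.weight)))
        for e in score_set.entries
    ]
    return ScoreSet(score_set.name, entries)
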