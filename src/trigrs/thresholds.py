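"""GRS cutoff analysis and the decision-aid rule.

A subject is recommended as a "likely responder" when their GRS is at
or below a calibrated cutoff.  The sweep enumerates every distinct GRS
value as a candidate cutoff and reports, per the study's quoted
conventions, the proportion of actual responders with a score at or
*below* the cutoff (``responders_captured``, which equals the rule's
sensitivity) and the proportion of actual nonresponders at or *above*
it; ties at the cutoff therefore count toward both quoted proportions.
Specificity uses the strict complement (GRS > cutoff).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["CutoffRow", "cutoff_sweep", "summary_points", "decision_aid", "DecisionRecord"]


@dataclass
class CutoffRow:
    cutoff: float
    sensitivity: float
    specificity: float
    responders_captured: float
    nonresponders_at_or_above: float
    n_responders: int
    n_nonresponders: int

    #: classification rule the row describes
    rule: str = "predict responder iff GRS <= cutoff"


def cutoff_sweep(grs, labels) -> list:
    """Sensitivity/specificity sweep over integer (or any) GRS cutoffs.

    ``labels`` marks responders (truthy).  One row per distinct GRS
    value, plus -inf and +inf sentinel rows.
    """
    grs = np.asarray(grs, dtype=float)
    resp = np.asarray(labels).astype(bool)
    if len(grs) == 0:
        raise ValueError("cutoff sweep requires at least one subject")
    n_r, n_nr = int(resp.sum()), int((~resp).sum())
    if n_r == 0 or n_nr == 0:
        warnings.warn(
            "only one class present: the missing class's proportions are undefined",
            stacklevel=2,
        )
    cutoffs = [-math.inf] + sorted(np.unique(grs)) + [math.inf]
    rows = []
    for c in cutoffs:
        captured = float(np.mean(grs[resp] <= c)) if n_r else math.nan
        at_or_above = float(np.mean(grs[~resp] >= c)) if n_nr else math.nan
        spec = float(np.mean(grs[~resp] > c)) if n_nr else math.nan
        rows.append(
            CutoffRow(
                cutoff=float(c),
                sensitivity=captured,
                specificity=spec,
                responders_captured=captured,
                nonresponders_at_or_above=at_or_above,
                n_responders=n_r,
                n_nonresponders=n_nr,
            )
        )
    return rows


def _nearest_rank(sorted_values: np.ndarray, q) -> float:
    n = len(sorted_values)
    rank = math.ceil(q * n)
    return float(sorted_values[max(rank, 1) - 1])


def summary_points(grs, labels) -> tuple:
    """Sweep rows at the bottom tertile, median and top tertile of the GRS.

    Tertile boundaries are the 1/3 and 2/3 nearest-rank sample quantiles
    of the GRS distribution; a constant GRS collapses all three points
    to one row with a warning.
    """
    grs = np.asarray(grs, dtype=float)
    if len(grs) < 3:
        raise ValueError("need at least 3 subjects for tertile summaries")
    ordered = np.sort(grs)
    bottom = _nearest_rank(ordered, 1 / 3)
    median = _nearest_rank(ordered, 1 / 2)
    top = _nearest_rank(ordered, 2 / 3)
    rows = {r.cutoff: r for r in cutoff_sweep(grs, labels)}
    if np.ptp(grs) == 0:
        warnings.warn("constant GRS: tertile points collapse to a single cutoff",
                      stacklevel=2)
    return rows[bottom], rows[median], rows[top]


@dataclass
class DecisionRecord:
    grs_value: float
    cutoff: float
    classification: str  # "likely-responder" / "likely-nonresponder"
    rationale: str


def decision_aid(grs_value: float, cutoff: float, sweep=None) -> DecisionRecord:
    """Classify one subject against a calibrated GRS cutoff.

    ``sweep`` (the output of :func:`cutoff_sweep` on the calibration
    cohort) enriches the rationale with the sensitivity and responder
    capture at the chosen cutoff.
    """
    likely = grs_value <= cutoff
    classification = "likely-responder" if likely else "likely-nonresponder"
    rationale = (
        f"GRS {grs_value:g} is {'at or below' if likely else 'above'} the cutoff "
        f"{cutoff:g}: {classification.replace('-', ' ')} to the n-3 FA supplementation"
    )
    if sweep is not None:
        row = next((r for r in sweep if r.cutoff == cutoff), None)
        if row is not None:
            rationale += (
                f" (at this cutoff sensitivity {row.sensitivity:.0%}, "
                f"{row.responders_captured:.0%} of actual responders captured, "
                f"specificity {row.specificity:.0%})"
            )
    return DecisionRecord(grs_value, cutoff, classification, rationale)
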