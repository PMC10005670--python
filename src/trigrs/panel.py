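"""The published fish-oil interaction SNP panel.

Seventeen SNPs — identified in a large biobank GWAS as interacting with
fish-oil supplementation on plasma lipid levels — were genotyped in the
FAS (Fatty Acid Sensor) supplementation trial (140 participants: 80
responders, 60 nonresponders after one genotyping failure).  Two proved
monomorphic in that cohort and were excluded by QC, leaving 15, of
which seven are specifically associated with plasma triglycerides.
This module packages the published per-SNP annotation (location, allele
orientation, overall MAF, HWE p), the per-group minor-allele
frequencies, and the published odds ratios and +/-1 scores, which serve
as the validation surface for the scoring pipeline and as the default
frequency panel of the synthetic cohort generator.

The two monomorphic proxies (rs147166404, rs530804537) have no
published genomic coordinates; the coordinates and alleles carried here
for them are synthetic placeholders (the ids and their monomorphic
status are the only facts the pipeline uses).
"""

from __future__ import annotations

import math

import pandas as pd

from .cohort import VariantRecord
from .scoring import ScoreEntry, ScoreSet, allele_odds_ratio, assign_score

__all__ = [
    "published_panel",
    "panel_variant_records",
    "tg_specific_ids",
    "monomorphic_ids",
    "default_additions",
    "score_published_panel",
]

# variant_id, chrom, pos, gene (location), major, minor, maf%, hwe_p, phenotype,
# maf_R, maf_NR, published OR, CI low, CI high, published score
_PANEL = [
    ("rs115675705", "6", 34094919, "GRM4 (intron)", "T", "C", 1.4, 1.0, "HDL",
     0.01, 0.02, 0.73, 0.10, 5.22, 1),
    ("rs117788606", "7", 72921771, "BAZ1B (intron)", "A", "G", 0.7, 1.0, "TG",
     0.01, 0.01, 0.74, 0.05, 11.9, 1),
    ("rs11983997", "7", 72939244, "BAZ1B (upstream)", "C", "G", 20.0, 0.2, "TG",
     0.18, 0.23, 0.73, 0.41, 1.32, 1),
    ("rs80189144", "7", 72939939, "BAZ1B (upstream)", "T", "C", 13.2, 0.1, "TG",
     0.12, 0.14, 0.84, 0.42, 1.68, 1),
    ("rs799157", "7", 73020301, "MLXIPL (synonymous)", "C", "T", 3.9, 1.0, "LDL",
     0.03, 0.05, 0.59, 0.18, 2.00, 1),
    ("rs117860853", "8", 19722204, "LPL (upstream)", "G", "A", 1.8, 1.0, "HDL",
     0.01, 0.03, 0.48, 0.08, 2.91, 1),
    ("rs142084074", "8", 19768150, "LOC107986921 (intron)", "G", "A", 0.7, 1.0, "TG",
     0.01, 0.01, 0.74, 0.05, 11.9, 1),
    ("rs144018203", "11", 116916060, "SIK3 (intron)", "G", "C", 0.7, 1.0, "HDL.TG",
     0.01, 0.01, 0.73, 0.04, 11.7, 1),
    ("rs112803755", "13", 20790451, "GJB6 (downstream)", "A", "G", 1.4, 1.0, "TG",
     0.01, 0.02, 0.74, 0.10, 5.31, 1),
    ("rs55707100", "15", 43820717, "MAP1A (missense)", "C", "T", 4.6, 1.0, "TG",
     0.06, 0.03, 1.71, 0.51, 5.68, -1),
    ("rs148931404", "16", 56914455, "SLC12A3 (intron)", "C", "T", 1.1, 1.0, "HDL",
     0.01, 0.01, 1.46, 0.13, 16.3, -1),
    ("rs147438979", "17", 42061277, "PYY (intron)", "G", "C", 1.8, 1.0, "HDL",
     0.02, 0.01, 2.96, 0.33, 26.9, -1),
    ("rs77542162", "17", 67081278, "ABCA6 (missense)", "T", "C", 0.4, 1.0, "LDL.TC",
     0.00, 0.01, math.nan, math.nan, math.nan, None),
    ("rs141844019", "19", 19365178, "HAPLN4 (downstream)", "G", "A", 1.1, 1.0, "TG",
     0.01, 0.01, 1.49, 0.13, 16.6, -1),
    ("rs112952132", "19", 45198060, "LOC107985305 (intron)", "G", "A", 0.7, 1.0, "LDL",
     0.01, 0.01, 0.73, 0.04, 11.7, 1),
]

# monomorphic in the trial cohort (no participant carried the rare allele);
# coordinates/alleles below are synthetic placeholders
_MONOMORPHIC = [
    ("rs147166404", "7", 72940500, "BAZ1B (proxy, synthetic coords)", "C", "T"),
    ("rs530804537", "8", 19769000, "LOC107986921 (proxy, synthetic coords)", "G", "A"),
]


def published_panel(include_monomorphic: bool = True) -> pd.DataFrame:
    """The published SNP panel as a DataFrame.

    Columns: annotation (``chromosome``, ``position``, alleles, gene,
    overall ``maf_pct``, ``hwe_p``, ``phenotype``), per-group MAFs
    (``maf_responders`` / ``maf_nonresponders`` as proportions), and the
    published ``published_or`` / CI / ``published_score``.
    """
    rows = []
    for rec in _PANEL:
        (vid, chrom, pos, gene, major, minor, maf_pct, hwe_p, pheno,
         maf_r, maf_nr, por, lo, hi, score) = rec
        rows.append(
            dict(variant_id=vid, chromosome=chrom, position=pos, nearest_gene=gene,
                 major_allele=major, minor_allele=minor, maf_pct=maf_pct, hwe_p=hwe_p,
                 phenotype=pheno, maf_responders=maf_r, maf_nonresponders=maf_nr,
                 published_or=por, published_ci_low=lo, published_ci_high=hi,
                 published_score=score)
        )
    if include_monomorphic:
        for vid, chrom, pos, gene, major, minor in _MONOMORPHIC:
            rows.append(
                dict(variant_id=vid, chromosome=chrom, position=pos, nearest_gene=gene,
                     major_allele=major, minor_allele=minor, maf_pct=0.0, hwe_p=1.0,
                     phenotype="", maf_responders=0.0, maf_nonresponders=0.0,
                     published_or=math.nan, published_ci_low=math.nan,
                     published_ci_high=math.nan, published_score=None)
            )
    return pd.DataFrame(rows)


def panel_variant_records(include_monomorphic: bool = True) -> list:
    """Panel annotation as :class:`VariantRecord` objects."""
    frame = published_panel(include_monomorphic)
    records = []
    for row in frame.itertuples(index=False):
        gene = row.nearest_gene.split(" (")[0]
        phenos = frozenset(p for p in str(row.phenotype).split(".") if p)
        records.append(
            VariantRecord(row.variant_id, row.chromosome, row.position,
                          major_allele=row.major_allele, minor_allele=row.minor_allele,
                          nearest_gene=gene, phenotypes=phenos)
        )
    return records


def monomorphic_ids() -> list:
    return [rec[0] for rec in _MONOMORPHIC]


def tg_specific_ids() -> list:
    """The seven panel SNPs specifically associated with plasma TG."""
    frame = published_panel(include_monomorphic=False)
    return frame.loc[frame.phenotype == "TG", "variant_id"].tolist()


def default_additions() -> dict:
    """Variant-id additions defining the extended score sets.

    ``GRS32`` adds the missense MAP1A SNP alone, ``GRS38`` the seven
    TG-specific SNPs, ``GRS46`` the full 15-SNP panel (one of which is
    excluded from scoring by the responder-MAF rule).
    """
    frame = published_panel(include_monomorphic=False)
    return {
        "GRS32": ["rs55707100"],
        "GRS38": tg_specific_ids(),
        "GRS46": frame.variant_id.tolist(),
    }


def score_published_panel(use_published_or: bool = True) -> tuple:
    """QC + scoring of the packaged panel.

    Monomorphic variants (overall MAF = 0) are excluded by QC.  The
    remaining variants are scored by the sign rule applied to the
    published odds ratios (the printed per-group MAF proportions are
    rounded to two decimals, so recomputing ORs from them is only
    faithful at the panel's mid-frequency SNPs; the published OR column
    is treated as input data).  With ``use_published_or=False`` the ORs
    are recomputed from the rounded proportions instead.

    Returns
    -------
    (ScoreSet, list)
        The score set over QC-passing variants (excluded-from-scoring
        entries carry ``score=None``) and the QC exclusion log.
    """
    frame = published_panel(include_monomorphic=True)
    qc_log, entries = [], []
    for row in frame.itertuples(index=False):
        if row.maf_responders == 0 and row.maf_nonresponders == 0:
            qc_log.append((row.variant_id, "monomorphic (MAF = 0)"))
            continue
        if use_published_or and not math.isnan(row.published_or):
            value, lo, hi = row.published_or, row.published_ci_low, row.published_ci_high
        elif row.maf_responders == 0:
            value, lo, hi = 0.0, math.nan, math.nan
        else:
            orr = allele_odds_ratio(row.maf_responders, row.maf_nonresponders)
            value, lo, hi = orr.value, orr.ci_low, orr.ci_high
        entries.append(
            ScoreEntry(row.variant_id, value, lo, hi,
                       score=assign_score(value, row.maf_responders))
        )
    return ScoreSet("panel", entries), qc_log
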