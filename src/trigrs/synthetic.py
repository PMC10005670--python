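"""Synthetic cohorts with the study's statistical structure.

The original trial data are not publicly released, so every pipeline
stage is exercised on generated cohorts that emulate the study
conditions: 80 responders and 60 nonresponders; genotypes drawn in
Hardy-Weinberg proportions within each group at the published per-group
minor-allele frequencies of the 17-SNP panel (two of them monomorphic);
an additional simulated base panel standing in for the original 31-SNP
score whose per-group frequency separation reproduces its strong
discrimination; TG changes of -0.50 +/- 0.36 mmol/L (responders,
truncated to satisfy the classification rule, by default with the >=10%
extreme-decrease requirement) and +0.18 +/- 0.17 mmol/L (nonresponders,
truncated at >= 0); log-normal baseline TG with a higher median among
responders; age uniform on 18-50 years and BMI on 25-40 kg/m2.

Variants are generated independently (no linkage disequilibrium): the
score treats SNPs independently and LD is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from . import io as tio
from .cohort import (
    Cohort,
    GenotypeMatrix,
    ResponseLabel,
    Sex,
    SubjectRecord,
    VariantRecord,
    classify_response,
)
from .panel import panel_variant_records, published_panel

__all__ = ["GeneratorConfig", "generate_cohort", "generate_null_pair", "write_fixture_bundle"]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort generator.

    ``variant_panel`` rows are ``(variant_id, maf_responders,
    maf_nonresponders)``; the default is the published 17-SNP panel
    (monomorphic proxies included).  ``base_grs_panel`` simulated
    variants emulate the original 31-SNP score with per-group MAFs
    ``base_maf_responders`` / ``base_maf_nonresponders`` (equal values
    give a null panel).
    """

    n_responders: int = 80
    n_nonresponders: int = 60
    variant_panel: Sequence[tuple] | None = None
    base_grs_panel: int = 31
    base_maf_responders: float = 0.20
    base_maf_nonresponders: float = 0.35
    tg_change_responders: tuple = (-0.50, 0.36)  # mean, sd (mmol/L)
    tg_change_nonresponders: tuple = (0.18, 0.17)
    baseline_tg_median: float = 1.3  # nonresponder median, mmol/L
    baseline_responder_ratio: float = 1.45  # responder/nonresponder median ratio
    baseline_log_sd: float = 0.30
    age_range: tuple = (18.0, 50.0)
    bmi_range: tuple = (25.0, 40.0)
    extreme_fraction: float = 0.10
    require_extreme: bool = True  # responders must show >= 10% relative decrease
    tg_floor: float = 0.05
    max_rejection: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.n_responders <= 0 or self.n_nonresponders <= 0:
            raise ValueError("group sizes must be positive")
        for _, sd in (self.tg_change_responders, self.tg_change_nonresponders):
            if sd <= 0:
                raise ValueError("TG-change standard deviations must be positive")
        for maf in (self.base_maf_responders, self.base_maf_nonresponders):
            if not 0 <= maf <= 0.5:
                raise ValueError("base-panel MAFs must be in [0, 0.5]")

    def resolved_panel(self) -> list:
        if self.variant_panel is not None:
            return list(self.variant_panel)
        frame = published_panel(include_monomorphic=True)
        return list(
            frame[["variant_id", "maf_responders", "maf_nonresponders"]].itertuples(
                index=False, name=None
            )
        )


def _base_variant_records(config: GeneratorConfig) -> list:
    records = []
    for j in range(config.base_grs_panel):
        records.append(
            VariantRecord(
                variant_id=f"sim_base_{j + 1:02d}",
                chromosome="1",
                position=1_000_000 * (j + 1),
                major_allele="A",
                minor_allele="G",
                nearest_gene="simulated",
            )
        )
    return records


def _draw_tg(rng, baseline, group, config: GeneratorConfig) -> float:
    mean, sd = (
        config.tg_change_responders
        if group == ResponseLabel.responder
        else config.tg_change_nonresponders
    )
    for _ in range(config.max_rejection):
        delta = rng.normal(mean, sd)
        post = baseline + delta
        if post < config.tg_floor:
            continue
        cls = classify_response((baseline, post), extreme_fraction=config.extreme_fraction)
        if cls.label != group:
            continue
        if group == ResponseLabel.responder and config.require_extreme and not cls.extreme:
            continue
        return post
    raise RuntimeError(
        f"could not draw a TG change satisfying the {group.value} rule after "
        f"{config.max_rejection} attempts; check the configured mean/sd"
    )


def generate_cohort(config: GeneratorConfig | None = None) -> Cohort:
    """Generate one cohort under the configured study conditions.

    Deterministic given ``config.seed``.  Genotypes at each variant are
    Binomial(2, group MAF) draws, i.e. Hardy-Weinberg-consistent within
    each response group.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)

    groups = [ResponseLabel.responder] * config.n_responders + [
        ResponseLabel.nonresponder
    ] * config.n_nonresponders
    n = len(groups)
    subject_ids = [f"S{i + 1:04d}" for i in range(n)]

    subjects = []
    for sid, group in zip(subject_ids, groups):
        age = rng.uniform(*config.age_range)
        bmi = rng.uniform(*config.bmi_range)
        sex = Sex.male if rng.random() < 0.5 else Sex.female
        median = config.baseline_tg_median * (
            config.baseline_responder_ratio if group == ResponseLabel.responder else 1.0
        )
        baseline = float(np.exp(rng.normal(np.log(median), config.baseline_log_sd)))
        post = _draw_tg(rng, baseline, group, config)
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                age=round(age, 1),
                sex=sex,
                bmi=round(bmi, 1),
                tg_baseline=round(baseline, 4),
                tg_post=round(post, 4),
                response_label=group,
            )
        )

    panel_rows = config.resolved_panel()
    known = {r.variant_id: r for r in panel_variant_records(include_monomorphic=True)}
    variant_records = list(_base_variant_records(config))
    mafs_r = [config.base_maf_responders] * config.base_grs_panel
    mafs_nr = [config.base_maf_nonresponders] * config.base_grs_panel
    for vid, maf_r, maf_nr in panel_rows:
        variant_records.append(
            known.get(vid)
            or VariantRecord(vid, "0", 1, major_allele="A", minor_allele="G",
                             nearest_gene="simulated")
        )
        mafs_r.append(float(maf_r))
        mafs_nr.append(float(maf_nr))

    is_resp = np.array([g == ResponseLabel.responder for g in groups])
    dosage = np.empty((n, len(variant_records)))
    for j, (maf_r, maf_nr) in enumerate(zip(mafs_r, mafs_nr)):
        column = np.empty(n)
        column[is_resp] = rng.binomial(2, maf_r, size=is_resp.sum())
        column[~is_resp] = rng.binomial(2, maf_nr, size=(~is_resp).sum())
        dosage[:, j] = column

    matrix = GenotypeMatrix(subject_ids, [v.variant_id for v in variant_records], dosage)
    return Cohort(subjects, variant_records, matrix)


def generate_null_pair(
    config: GeneratorConfig | None = None, n_reps: int = 100, seed: int = 0
) -> Iterator[Cohort]:
    """Stream of permutation-null cohorts sharing one genotype matrix.

    The base cohort is generated once from ``config``; each yielded
    cohort reassigns whole phenotype records (response label, TG values
    and covariates together, so every record stays internally consistent
    with the classification rule) to genotype rows by an independent
    random permutation.  The genotype matrix is identical across the
    stream; deterministic given ``seed``.
    """
    config = config or GeneratorConfig()
    base = generate_cohort(config)
    rng = np.random.default_rng(seed)
    ids = [s.subject_id for s in base.subjects]
    for _ in range(n_reps):
        perm = rng.permutation(len(ids))
        records = [
            replace(base.subjects[perm[i]], subject_id=ids[i]) for i in range(len(ids))
        ]
        yield Cohort(records, base.variants, base.genotypes)


def write_fixture_bundle(cohort: Cohort, directory) -> list:
    """Write the full text fixture set for a cohort.

    Emits the PLINK ``.ped``/``.map`` pair, a VCF, the phenotype TSV,
    the variant annotation TSV, and the published score-table reference
    TSV; every file round-trips through :mod:`trigrs.io`.

    Returns the list of paths written.
    """
    if cohort.n_subjects == 0 or cohort.n_variants == 0:
        raise ValueError("cannot write a fixture bundle for an empty cohort")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "ped": directory / "genotypes.ped",
        "map": directory / "genotypes.map",
        "vcf": directory / "genotypes.vcf",
        "pheno": directory / "phenotypes.tsv",
        "annot": directory / "variants.tsv",
        "scores": directory / "published_scores.tsv",
    }
    tio.write_plink_text(cohort, paths["ped"], paths["map"])
    tio.write_vcf(cohort, paths["vcf"])
    tio.write_phenotypes(cohort.subjects, paths["pheno"])
    tio.write_annotation(cohort.variants, paths["annot"])
    published_panel(include_monomorphic=True).to_csv(
        paths["scores"], sep="\t", index=False, float_format="%.6g"
    )
    return [paths[k] for k in ("ped", "map", "vcf", "pheno", "annot", "scores")]
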