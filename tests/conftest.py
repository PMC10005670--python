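import numpy as np
import pytest

from trigrs.cohort import Cohort, GenotypeMatrix, ResponseLabel, SubjectRecord, VariantRecord
from trigrs.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort (80 responders / 60 nonresponders)."""
    return generate_cohort(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def base_variant_ids(default_cohort):
    return [
        v.variant_id
        for v in default_cohort.variants
        if v.variant_id.startswith("sim_base")
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """A small, fast cohort for IO round-trip tests."""
    config = GeneratorConfig(
        n_responders=6,
        n_nonresponders=4,
        base_grs_panel=3,
        variant_panel=[("rs11983997", 0.25, 0.35), ("rs55707100", 0.10, 0.05)],
        seed=5,
    )
    return generate_cohort(config)


def toy_cohort(dosage, labels, variant_ids=None):
    """Hand-built cohort from a dosage matrix and responder flags."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    variant_ids = variant_ids or [f"v{j + 1}" for j in range(m)]
    subjects = [
        SubjectRecord(
            f"s{i + 1}",
            response_label=(
                ResponseLabel.responder if labels[i] else ResponseLabel.nonresponder
            ),
        )
        for i in range(n)
    ]
    variants = [
        VariantRecord(vid, "1", 100 + j, major_allele="A", minor_allele="G")
        for j, vid in enumerate(variant_ids)
    ]
    matrix = GenotypeMatrix([s.subject_id for s in subjects], variant_ids, dosage)
    return Cohort(subjects, variants, matrix)
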