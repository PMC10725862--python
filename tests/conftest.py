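import warnings

import numpy as np
import pytest

from brainagemci.brainage import classify_cohort
from brainagemci.pipeline import run_analysis
from brainagemci.synth import (
    GeneratorConfig,
    generate_cohort,
    generate_reference,
    score_generated_cohort,
)

COHORT_SEED = 1234


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort(default_config):
    """Default synthetic study cohort: (records, volumes, ground truth)."""
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def scored(default_config, cohort):
    """(brain-age results, normative model, weights) for the default cohort."""
    records, volumes, _ = cohort
    rng = np.random.default_rng(COHORT_SEED + 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return score_generated_cohort(records, volumes, default_config, rng)


@pytest.fixture(scope="session")
def classification(cohort, scored):
    records, _, _ = cohort
    results, _, _ = scored
    return classify_cohort(results, {r.subject_id: r.converted for r in records})


@pytest.fixture(scope="session")
def bundle(default_config, cohort):
    """Full analysis bundle for the default cohort."""
    records, volumes, _ = cohort
    rng = np.random.default_rng(COHORT_SEED + 2)
    reference, ref_ages, ref_sexes = generate_reference(default_config, rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_analysis(
            records, volumes, reference, ref_ages, ref_sexes, seed=COHORT_SEED
        )
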