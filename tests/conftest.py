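"""Shared fixtures: a small synthetic cohort and a fitted pipeline on it.

Sizes are deliberately small (240 patients, ~3k notes, 120-word vocabulary,
6 planted topics) so the whole unit suite stays fast; statistical
assertions at this scale are the ones the generator's planted structure
makes separable by design.
"""

import pytest

from phenorisk.pipeline import PipelineConfig, run_pipeline
from phenorisk.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(
        n_cases=60, n_controls=60, n_validation_controls=120,
        race_strata=("BA",), notes_per_year=4.0, vocab_size=120,
        n_topics_true=6, signal_topic_ids=(0, 1), latent_prevalence=0.1,
        note_length=(30, 80), seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    # verify=True asserts every emitted patient passes check_eligibility
    return generate_cohort(small_config, verify=True)


@pytest.fixture(scope="session")
def small_pipeline(small_cohort):
    pipe = PipelineConfig(K=10, learn_fraction=1.0, lda_max_iter=10,
                          min_support=5, seed=7)
    return run_pipeline(cohort=small_cohort, pipe=pipe)
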