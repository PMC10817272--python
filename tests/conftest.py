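import numpy as np
import pytest

from ehrisk import synthetic_ehr as se
from ehrisk.pipeline import prepare_encoded_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-patient synthetic cohort pushed through cohort rules, NLP and
    encoding; shared across tests that only read from it."""
    (timelines, truth, samples, exclusions, encoded, vocab, sdoh_encoder,
     therapy_flags) = prepare_encoded_cohort(seed=11, n_patients=300,
                                             min_lab_freq=20)
    return {
        "timelines": timelines, "truth": truth, "samples": samples,
        "exclusions": exclusions, "encoded": encoded, "vocab": vocab,
        "sdoh_encoder": sdoh_encoder, "therapy_flags": therapy_flags,
    }


@pytest.fixture(scope="session")
def mid_cohort_raw():
    """2000 simulated timelines + ground truth (no downstream processing)."""
    cfg = se.default_config(2000, seed=23)
    sdoh = se.generate_sdoh_table(cfg)
    timelines, truth = se.generate_cohort(cfg, sdoh)
    return cfg, sdoh, timelines, truth
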