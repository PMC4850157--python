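import numpy as np
import pandas as pd
import pytest

from frsp.io import RunConfig
from frsp.reading import (
    ConditionScanpath,
    ScanpathConfig,
    StimulusQuadruple,
    generate_corpus,
)


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(n_quads=12, seed=11)


@pytest.fixture
def quad():
    return StimulusQuadruple(
        quad_id=0,
        words_ord=(3, 5, 7, 4, 6, 5),
        words_rdm=(5, 6, 7, 4, 3, 5),
        target_index=2,
    )


@pytest.fixture
def deterministic_cfg():
    """Scanpath config with no skipping, refixations or regressions."""
    cond = ConditionScanpath(200.0, 0.0, 150.0, 0.0, 150.0)
    return ScanpathConfig(
        conditions={c: cond for c in ("ORD_COR", "ORD_SEM", "RDM_COR", "RDM_SEM")},
        skip_prob_target=0.0,
        skip_prob_other=0.0,
    )


@pytest.fixture
def mini_run_config():
    """Small full-pipeline configuration for smoke tests."""
    return RunConfig(subjects=4, n_quads=6, session_quads=4)


def make_fixations(rows):
    """rows: (subject, trial, condition, word, onset, duration, pass_label)."""
    return pd.DataFrame(
        rows,
        columns=[
            "subject", "trial", "condition", "word_index",
            "onset_ms", "duration_ms", "pass_label",
        ],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
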