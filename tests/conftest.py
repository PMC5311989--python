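import numpy as np
import pandas as pd
import pytest

from mddtool import ConfusionTable, GeneratorConfig, default_bank


@pytest.fixture(scope="session")
def bank():
    return default_bank()


@pytest.fixture(scope="session")
def study_table():
    """The all-patients confusion table of the emulated validation study:
    35 reference-positive of 179, 17 true positives, 10 false positives."""
    return ConfusionTable(tp=17, fn=18, fp=10, tn=134)


@pytest.fixture(scope="session")
def default_cfg():
    return GeneratorConfig()


@pytest.fixture()
def study_cohort_df():
    """A paired-diagnosis table realising the study counts, with BDI totals
    placed mid-band so each reference-positive falls in a known stratum."""
    rows = []
    rid = 0

    def add(n, index, ref, bdi):
        nonlocal rid
        for _ in range(n):
            rid += 1
            rows.append(
                {
                    "respondent_id": f"r{rid:03d}",
                    "index_test": index,
                    "reference": ref,
                    "bdi_total": bdi,
                }
            )

    # reference-positives by severity band: 14 mild, 12 moderate, 9 severe
    # detected counts 3/7/7 sum to TP=17 (FN=18)
    add(3, "positive", "positive", 16)
    add(11, "negative", "positive", 16)
    add(7, "positive", "positive", 24)
    add(5, "negative", "positive", 24)
    add(7, "positive", "positive", 33)
    add(2, "negative", "positive", 33)
    # reference-negatives: FP=10, TN=134, low BDI
    add(10, "positive", "negative", 5)
    add(134, "negative", "negative", 5)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230216)
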