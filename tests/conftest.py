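import numpy as np
import pandas as pd
import pytest

from cyclevag.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default 61-woman cohort, generated once per session."""
    config = CohortConfig(seed=11)
    counts, hormones, metadata, truth = generate_cohort(config)
    return {
        "config": config,
        "counts": counts,
        "hormones": hormones,
        "metadata": metadata,
        "truth": truth,
    }


@pytest.fixture()
def toy_counts():
    """4 samples x 3 taxa with simple hand-checkable structure."""
    counts = pd.DataFrame(
        [[10, 30, 60], [100, 0, 0], [5, 5, 0], [1, 1, 1]],
        index=["W1_1", "W1_2", "W2_1", "W2_2"],
        columns=["A", "B", "C"],
        dtype=np.int64,
    )
    counts.index.name = "sample_id"
    return counts


@pytest.fixture()
def toy_design():
    return pd.DataFrame(
        {
            "woman": ["W1", "W1", "W2", "W2"],
            "visit_number": [1, 2, 1, 2],
            "phase": ["follicular", "ovulatory", "follicular", "ovulatory"],
        },
        index=["W1_1", "W1_2", "W2_1", "W2_2"],
    )
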