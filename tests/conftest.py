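import numpy as np
import pandas as pd
import pytest

from angoffsim import AngoffExperiment
from angoffsim.grid import RESULT_COLUMNS


@pytest.fixture(scope="session")
def published_results():
    """Full default 49x100 grid under the published-results conditions."""
    return AngoffExperiment.as_published().run(seed=0)


@pytest.fixture(scope="session")
def published_table(published_results):
    return published_results.table


@pytest.fixture()
def rng():
    return np.random.default_rng(20160504)


def make_table(n_panels: int, rng: np.random.Generator) -> pd.DataFrame:
    """Small synthetic results table satisfying the schema invariants."""
    rows = []
    for i in range(n_panels):
        s1 = rng.normal(scale=0.1)
        s2 = s1 * (1 + 0.05 * rng.normal())
        rows.append(
            {
                "n_judges": 5 + (i % 3) * 5,
                "n_items": 10,
                "replicate_id": i,
                "seed": 0,
                "score1": s1,
                "score2": s2,
                "abs_score1": abs(s1),
                "abs_score2": abs(s2),
                "within_panel_sd": abs(rng.normal(0.3, 0.05)),
                "mean_accuracy": abs(rng.normal(0.8, 0.2)),
                "mean_stringency": rng.normal(),
                "mean_leadership": rng.normal(),
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


@pytest.fixture()
def small_table(rng):
    return make_table(40, rng)
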