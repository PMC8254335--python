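import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from posrate.types import Pair, PairedExpressionCohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_paired_cohort(diffs: np.ndarray, cohort_id: str = "toy", rng=None) -> PairedExpressionCohort:
    """Build a paired cohort whose tumor - adjacent differences equal ``diffs``
    (genes x pairs); adjacent baselines are arbitrary."""
    rng = rng or np.random.default_rng(0)
    n_genes, n_pairs = diffs.shape
    adjacent = rng.normal(8, 1, size=diffs.shape)
    tumor = adjacent + diffs
    genes = [f"g{i}" for i in range(n_genes)]
    pairs, cols, data = [], [], []
    for j in range(n_pairs):
        pairs.append(Pair(f"s{j}", f"s{j}_T", f"s{j}_A"))
        cols += [f"s{j}_T", f"s{j}_A"]
        data += [tumor[:, j], adjacent[:, j]]
    expr = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    return PairedExpressionCohort(cohort_id, expr, pairs)


@pytest.fixture
def paired_cohort_factory():
    return make_paired_cohort
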