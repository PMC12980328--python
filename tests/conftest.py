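import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cccoef import FeatureVector, generate_dataset


@pytest.fixture(scope="session")
def suite():
    """Default 12-feature synthetic motif suite (one pair per pattern)."""
    return generate_dataset(1, n_null_features=0, n_samples=200, seed=1234)


@pytest.fixture(scope="session")
def suite_features(suite):
    return [
        FeatureVector.from_numerical(str(fid), suite.expression.loc[fid].to_numpy())
        for fid in suite.expression.index
    ]


def set_partitions_upto_k(n, k_max):
    """All set partitions of range(n) into at most k_max non-empty blocks,
    as label vectors in restricted-growth (first-occurrence) form."""
    out = []

    def rec(labels, used):
        i = len(labels)
        if i == n:
            out.append(np.array(labels, dtype=np.int64))
            return
        for lab in range(min(used + 1, k_max)):
            rec(labels + [lab], max(used, lab + 1))

    rec([], 0)
    return out
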