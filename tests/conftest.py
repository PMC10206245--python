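import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mircornet.containers import CountMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_count_matrix(
    values, feature_ids=None, n_fh=None, n_sfh=None, feature_kind="miRNA"
):
    """CountMatrix from a 2-D array; first n_fh columns are FH samples."""
    values = np.asarray(values)
    n_samples = values.shape[1]
    if n_fh is None:
        n_fh = n_samples // 2
    if n_sfh is None:
        n_sfh = n_samples - n_fh
    samples = [f"FH{i+1}" for i in range(n_fh)] + [f"SFH{i+1}" for i in range(n_sfh)]
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(values.shape[0])]
    groups = pd.Series(["FH"] * n_fh + ["SFH"] * n_sfh, index=samples, dtype=object)
    return CountMatrix(
        pd.DataFrame(values, index=feature_ids, columns=samples),
        groups,
        feature_kind,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_counts(rng):
    """200 x 14 NB-ish random count matrix, 7 FH + 7 SFH samples."""
    vals = rng.negative_binomial(5, 0.05, size=(200, 14))
    return make_count_matrix(vals)


# small synthetic configuration shared by pipeline-level tests: scaled down
# so a full run stays in the seconds range
SMALL_SYNTH = dict(
    n_mirna=60,
    n_gene=90,
    n_low_mirna=30,
    n_zero_mirna=5,
    frac_de_mirna=12 / 60,
    n_target_pairs=16,
    n_regulators=8,
)
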