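from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from methtdm.containers import OmicsMatrix

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")


def make_omics(values, feature_ids=None, case=None, control=None) -> OmicsMatrix:
    """Small OmicsMatrix with auto-generated IDs/labels."""
    arr = np.asarray(values, dtype=float)
    n_feat, n_samp = arr.shape
    feature_ids = feature_ids or [f"F{i+1}" for i in range(n_feat)]
    if case is None and control is None:
        case = [f"PE{i+1:02d}" for i in range(max(n_samp - 2, 2))]
        control = [f"CT{i+1:02d}" for i in range(n_samp - len(case))]
    samples = list(case) + list(control)
    labels = pd.Series(["case"] * len(case) + ["control"] * len(control),
                       index=samples)
    df = pd.DataFrame(arr, index=feature_ids, columns=samples)
    return OmicsMatrix(df, labels)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
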