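import numpy as np
import pandas as pd
import pytest

import mirnaboot as mb


@pytest.fixture(scope="session")
def null_cohort():
    """Default synthetic cohort with no planted structure."""
    cfg = mb.null_config(seed=42)
    mat, meta, annot = mb.simulate_cohort(cfg)
    return cfg, mat, meta, annot


@pytest.fixture(scope="session")
def null_expr(null_cohort):
    _, mat, meta, _ = null_cohort
    return mb.preprocess(mat), meta


@pytest.fixture()
def two_group_frame():
    """Minimal expr/meta pair with an HEa vs UE layout for effect sizes."""
    rng = np.random.default_rng(7)
    n_x, n_y = 24, 25
    meta = pd.DataFrame(
        {
            "group": ["HEa"] * n_x + ["UE"] * n_y,
            "sex": ["M"] * (n_x + n_y),
            "time_point": ["T2"] * (n_x + n_y),
        },
        index=[f"S{i:03d}" for i in range(n_x + n_y)],
    )
    expr = mb.NormalizedExpression(
        pd.DataFrame({"m1": rng.normal(size=n_x + n_y)}, index=meta.index)
    )
    return expr, meta
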