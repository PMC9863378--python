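import numpy as np
import pandas as pd
import pytest

import qsarpt as q


@pytest.fixture(scope="session")
def bundle():
    """One complete synthetic study (15 compounds x 5 replicates)."""
    return q.paperlike_study(seed=1)


@pytest.fixture(scope="session")
def scaled(bundle):
    return q.scale_matrix(bundle.chromatographic)


@pytest.fixture()
def tiny_matrix():
    """5 compounds x 4 descriptors with hand-set values."""
    schema = q.DescriptorSchema(
        tuple(
            q.io.DescriptorEntry(c, "physicochemical")
            for c in ("D1", "D2", "D3", "D4")
        )
    )
    rng = np.random.default_rng(42)
    values = rng.normal(size=(5, 4))
    return q.DescriptorMatrix([f"C{i}" for i in range(5)], schema, values)


def make_clearance(compounds, means, n_reps=5, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for comp, mu in zip(compounds, means):
        for r in range(1, n_reps + 1):
            ci = mu + (rng.normal(0, noise) if noise else 0.0)
            rows.append({"compound_id": comp, "replicate_id": r, "ci": max(ci, 0.011)})
    return q.ClearanceTable(pd.DataFrame(rows))
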