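import numpy as np
import pandas as pd
import pytest

from berrychron import AbundanceMatrix, SampleDesign


def make_design(n_stages=4, n_reps=3, stages=None, fw=None, is_ref=None, ti_ref=None):
    """Small balanced design with configurable normalizers."""
    stages = stages or [f"S{i + 1}" for i in range(n_stages)]
    rows = []
    for stage in stages:
        for rep in range(1, n_reps + 1):
            rows.append(
                {
                    "sample_id": f"{stage}_r{rep}",
                    "stage": stage,
                    "replicate": str(rep),
                    "fresh_weight": 1.0,
                    "internal_standard_intensity": 1.0,
                    "total_ion_intensity": 1.0,
                }
            )
    table = pd.DataFrame(rows).set_index("sample_id")
    if fw is not None:
        table["fresh_weight"] = fw
    if is_ref is not None:
        table["internal_standard_intensity"] = is_ref
    if ti_ref is not None:
        table["total_ion_intensity"] = ti_ref
    return SampleDesign(table, stage_order=stages)


def make_matrix(values, design, kind="metabolite_gc", feature_ids=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    feature_ids = feature_ids or [f"f{i + 1}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=feature_ids, columns=design.samples)
    return AbundanceMatrix(df, pd.Series(kind, index=feature_ids))


@pytest.fixture
def design4x3():
    return make_design(4, 3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
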