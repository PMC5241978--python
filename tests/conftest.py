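import numpy as np
import pandas as pd
import pytest

from sigstrat import Cohort, ScaleDefinition, Signature


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def panss_scale():
    """A 30-item scale with 7/7/16 domain groupings and a shared 1-7 range."""
    pos = tuple(f"p{i}" for i in range(1, 8))
    neg = tuple(f"n{i}" for i in range(1, 8))
    gen = tuple(f"g{i}" for i in range(1, 17))
    return ScaleDefinition(
        name="panss",
        items=pos + neg + gen,
        domains={"positive": pos, "negative": neg, "general": gen},
        item_range=(1.0, 7.0),
    )


@pytest.fixture
def small_scale():
    return ScaleDefinition(
        name="mini",
        items=("a", "b", "c"),
        domains={"first": ("a", "b"), "second": ("c",)},
    )


@pytest.fixture
def small_cohort(small_scale):
    sigs = (
        Signature("p1", "t1", [1.0, 2.0, 3.0]),
        Signature("p2", "t1", [4.0, 5.0, 6.0]),
        Signature("p1", "t2", [0.5, 1.5, 2.5]),
        Signature("p2", "t2", [2.0, 2.0, 2.0]),
    )
    return Cohort(small_scale, sigs)


@pytest.fixture
def wide_csv(tmp_path, panss_scale, rng):
    """A valid wide-layout cohort file for 4 patients at one timepoint."""
    values = rng.integers(1, 8, size=(4, 30)).astype(float)
    df = pd.DataFrame(values, columns=list(panss_scale.items))
    df.insert(0, "timepoint", "t1")
    df.insert(0, "patient_id", [f"p{i}" for i in range(1, 5)])
    path = tmp_path / "cohort.csv"
    df.to_csv(path, index=False)
    return path, df
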