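import numpy as np
import pandas as pd
import pytest

from metabextract.feature_io import FeatureTable


def make_table(areas, feature_meta=None, sample_meta=None):
    """Build a FeatureTable from plain dicts/arrays (test helper).

    ``areas``: dict feature_id -> list of areas, or DataFrame.
    ``sample_meta``: list of (sample_id, group, sample_type, injection_order).
    """
    if not isinstance(areas, pd.DataFrame):
        areas = pd.DataFrame.from_dict(areas, orient="index")
    n_feat, n_samp = areas.shape
    if sample_meta is None:
        sample_meta = [(f"S{i+1}", "I", "STUDY", i + 1) for i in range(n_samp)]
    sample_ids = [s[0] for s in sample_meta]
    areas.columns = sample_ids
    samples = pd.DataFrame({
        "group": [s[1] for s in sample_meta],
        "sample_type": [s[2] for s in sample_meta],
        "injection_order": [s[3] for s in sample_meta],
        "column": "RP_PHENYL_HEXYL",
        "polarity": "POS",
    }, index=pd.Index(sample_ids, name="sample_id"))
    if feature_meta is None:
        feature_meta = pd.DataFrame({
            "mz": np.linspace(100, 500, n_feat),
            "rt": np.linspace(30, 300, n_feat),
            "annotation": [""] * n_feat,
        }, index=areas.index)
    feature_meta.index.name = "feature_id"
    return FeatureTable(areas, feature_meta, samples)


@pytest.fixture
def tiny_table():
    """3 features x 4 samples (3 study in two groups + 1 QC), one missing cell."""
    return make_table(
        {"fA": [100.0, 110.0, 205.0, 150.0],
         "fB": [50.0, np.nan, 48.0, 49.0],
         "fC": [0.0, 5.0, 7.0, 4.0]},
        sample_meta=[("s1", "I", "STUDY", 1), ("s2", "I", "STUDY", 2),
                     ("s3", "III", "STUDY", 3), ("qc1", "QC", "QC", 4)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
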