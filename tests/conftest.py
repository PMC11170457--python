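import numpy as np
import pandas as pd
import pytest

from actijive import blocks, simulate
from actijive.epoch import EpochSeries


@pytest.fixture(scope="session")
def default_epoch_cohort():
    """Reference-calibrated epoch-tier cohort (200 subjects x 14 days) with
    its extracted features; shared by the recovery tests."""
    plan = simulate.EpochPlan(n_subjects=200, n_days=14)
    series, annotations, truth = simulate.generate_epoch_cohort(plan, seed=20240612)
    cfg = blocks.FeatureConfig(fragmentation_wake_only=True)
    feats, meta = blocks.extract_features(series, cfg)
    return {"plan": plan, "series": series, "annotations": annotations,
            "truth": truth, "features": feats.data, "meta": meta}


def make_series(subject="S1", n_days=1, counts=None, wear=None,
                start="2020-01-06 12:00") -> EpochSeries:
    n = n_days * 1440
    if counts is None:
        counts = np.zeros(n)
    if wear is None:
        wear = np.ones(n, dtype=bool)
    return EpochSeries(subject, pd.Timestamp(start), np.asarray(counts, float),
                       np.asarray(wear, bool))


settings_profile_registered = False
try:
    from hypothesis import settings as _hs
    _hs.register_profile("deterministic", derandomize=True)
    _hs.load_profile("deterministic")
    settings_profile_registered = True
except ImportError:  # pragma: no cover
    pass
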