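import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from metamediate import SimConfig, StudyRecord, EffectEntry, generate_meta_dataset
from metamediate.effects import build_correlation_sets
from metamediate.stage1 import PooledCorrelations


def make_record(study_id="S1", n=100, pairs=None, **kwargs):
    """Study with plain correlation entries, pairs = {'XM': 0.2, ...}."""
    pairs = pairs or {"XM": 0.2, "XY": 0.2, "MY": 0.2}
    entries = [
        EffectEntry(study_id, pair, "correlation", value=v)
        for pair, v in pairs.items()
    ]
    return StudyRecord(study_id=study_id, n=n, entries=entries, **kwargs)


@pytest.fixture
def reference_paths():
    """Generative paths of the reference mediation system."""
    return np.array([0.21, 0.25, 0.18])


@pytest.fixture
def reference_triple():
    """Correlation triple implied by the reference paths (path tracing)."""
    return np.array([0.21, 0.2325, 0.2878])


@pytest.fixture
def small_meta():
    """A small fast-mode synthetic meta-analysis and its correlation sets."""
    records = generate_meta_dataset(SimConfig(K=30, seed=7, mode="fast"))
    return records, build_correlation_sets(records)


def pooled_from_triple(rho, n_total=10_000):
    """Pooled result with a normal-theory acov, for Stage-2 unit tests."""
    from metamediate.stage1 import correlation_acov

    rho = np.asarray(rho, dtype=float)
    return PooledCorrelations(
        rho=rho,
        acov=correlation_acov(rho, n_total),
        tau2=np.zeros(3),
        fe_rho=rho,
        n_studies=1,
        n_total=n_total,
        n_observed=3,
    )
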