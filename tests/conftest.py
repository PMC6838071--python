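import numpy as np
import pandas as pd
import pytest

from pdcscreen import synthetic


def make_candidate(**overrides) -> dict:
    """A candidate that passes every filter criterion unless overridden."""
    base = {
        "chrom": "chr1",
        "pos": 1000,
        "ref": "C",
        "alt": "T",
        "tumor_depth": 200,
        "tumor_alt_reads": 20,
        "tumor_vaf": 0.10,
        "normal_vaf": 0.00,
        "strand_bias": 0.60,
        "population_freq": 0.001,
        "effect_class": "missense",
        "near_repeat": False,
    }
    base.update(overrides)
    return base


@pytest.fixture
def passing_candidate() -> pd.DataFrame:
    return pd.DataFrame([make_candidate()])


@pytest.fixture
def small_cohort_candidates() -> pd.DataFrame:
    spec = synthetic.CohortSpec(n_samples=30, seed=7)
    return synthetic.generate_variant_candidates(spec, artifact_rate=0.25)


@pytest.fixture
def small_panel():
    return synthetic.PanelSpec(cv_noise=0.05)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
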