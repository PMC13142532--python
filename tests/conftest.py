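import numpy as np
import pandas as pd
import pytest

from mcprogram import pseudobulk, synthgen


@pytest.fixture(scope="session")
def small_cohort():
    """Default synthetic cohort shared by read-only tests."""
    cfg = synthgen.SimConfig(seed=7)
    return synthgen.generate_pseudobulk_cohort(cfg)


@pytest.fixture(scope="session")
def fitted_model(small_cohort):
    from mcprogram import factorize

    pb, gt = small_cohort
    views = {ct: np.log1p(v[pseudobulk.qc_filter_genes(v)])
             for ct, v in pseudobulk.qc_filter_samples(pb).views.items()}
    return factorize.fit_factors(views, pb.meta["group"], n_factors=10), views


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def toy_visits():
    """Hand-written visit table with known labels."""
    return pd.DataFrame({
        "patient_id": ["A", "A", "A", "B", "B", "C"],
        "day": [0, 60, 160, 0, 200, 0],
        "SLEDAI": [1, 6, 1, 1, 1, 2],
    })
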