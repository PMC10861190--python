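import dataclasses

import numpy as np
import pandas as pd
import pytest

from prosteo import synth
from prosteo.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with strong planted signal, shared across tests."""
    cfg = synth.SynthConfig(
        n_participants=300, n_proteins=30, n_bmd_proteins=8, n_age_proteins=8, seed=7
    )
    return synth.generate_cohort(cfg)


@pytest.fixture(scope="session")
def pipeline_bundle():
    """One full desk-scale pipeline run (n=800, 60 proteins, 3 visits).

    Session-scoped: the run is the end-to-end smoke condition and several
    tests inspect different parts of the same bundle.
    """
    cfg = PipelineConfig(seed=0)
    assert cfg.synth.n_participants == 800 and cfg.synth.n_proteins == 60
    return run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_protein_frame(values, columns=None):
    arr = np.asarray(values, dtype=float)
    cols = columns or [f"P{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=cols)
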