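import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

import paradiomics as pr


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_voi(rng):
    """Random 4x4x3 volume with a ragged mask for oracle comparisons."""
    values = rng.normal(size=(4, 4, 3))
    mask = rng.random((4, 4, 3)) < 0.8
    mask[1, 1, 1] = True
    return values, mask


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """One full study-sized pipeline run shared by the end-to-end tests.

    Default conditions: 10 basal + 11 luminal specimens, 9 wavelengths,
    6 grey-level settings, 2 reconstruction surrogates, 5 folds.
    """
    out = tmp_path_factory.mktemp("study")
    config = pr.RunConfig(seed=11, output_dir=str(out), persist_volumes=False)
    manifest = pr.run_pipeline(config)
    return {
        "config": config,
        "manifest": manifest,
        "dir": out,
        "table": pd.read_csv(out / "features_long.csv"),
        "eta2": pd.read_csv(out / "eta2.csv", index_col=0),
    }
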