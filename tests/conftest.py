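import numpy as np
import pandas as pd
import pytest

from rhizometa import synth


@pytest.fixture(scope="session")
def small_bundle() -> synth.StudySet:
    """A small but complete multi-study bundle shared by read-only tests."""
    cfg = synth.SynthConfig(n_studies=6, samples_per_group=4, n_taxa=120,
                            depth_mean=6000.0, seed=1234)
    return synth.generate_study_set(cfg)


@pytest.fixture()
def toy_counts() -> pd.DataFrame:
    rng = np.random.default_rng(7)
    return pd.DataFrame(
        rng.integers(0, 50, size=(6, 10)),
        index=[f"s{i}" for i in range(6)],
        columns=[f"t{j}" for j in range(10)],
    )
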