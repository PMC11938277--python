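import numpy as np
import pytest

from nmrlogd.chemio import label_slice
from nmrlogd.mlmodel import Dataset
from nmrlogd.spectra import bucketize
from nmrlogd.synthgen import SynthConfig, generate_hose_world, generate_library


@pytest.fixture(scope="session")
def hose_world():
    """Default template molecules with mapped shifts plus held-out graphs."""
    return generate_hose_world()


@pytest.fixture(scope="session")
def small_library():
    """A 40-compound synthetic library (fast enough for unit tests)."""
    cfg = SynthConfig(n_compounds=40, seed=11)
    return cfg, *generate_library(cfg)


def make_dataset(n_compounds: int, seed: int, label_noise_rel: float = 0.3,
                 parameter: str = "CHI", ph: float = 7.4,
                 source: str = "pseudo") -> Dataset:
    """Bucketized synthetic library as one ML-ready dataset slice."""
    cfg = SynthConfig(n_compounds=n_compounds, seed=seed,
                      label_noise_rel=label_noise_rel)
    _, shift_lists, labels = generate_library(cfg)
    X = np.vstack([bucketize(sl).counts for sl in shift_lists]).astype(float)
    y = label_slice(labels, parameter, ph)
    return Dataset(X=X, y=y.to_numpy(),
                   compound_ids=[sl.compound_id for sl in shift_lists],
                   source=source)
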