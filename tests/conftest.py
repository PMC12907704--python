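import numpy as np
import pandas as pd
import pytest

from cfdeconv import autoencoder as ae
from cfdeconv import fixtures as fx
from cfdeconv import simulate as sim

# study-scale deconvolution fixture: 200 selected probes, 1,000 training
# mixtures, 256 epochs — shared across recovery/monotonicity/atlas tests
DECONV_SPEC = fx.FixtureSpec(
    n_probes=200, n_dmp=200, n_tissue_dmp=0, n_tumor=30, n_plasma=30, seed=3
)
TRAIN_N = 1000
HELDOUT_N = 200


@pytest.fixture(scope="session")
def deconv_reference():
    """Reference matrix + true population means for the deconvolution fixture."""
    ref, true_means, planted = fx.make_reference(DECONV_SPEC)
    return ref, true_means, planted


@pytest.fixture(scope="session")
def trained_bundle(deconv_reference):
    """One fully trained model shared by the slow deconvolution tests.

    Trains on 1,000 Dirichlet mixtures over the 200-probe fixture for the
    default 256 epochs; also returns 200 held-out mixtures from an
    independent seed.
    """
    ref, true_means, _ = deconv_reference
    train_set = sim.generate_simulated_data(ref, samplenum=TRAIN_N, random_state=1)
    model, history = ae.train(train_set.x, train_set.y, ref, seed=1)
    heldout = sim.generate_simulated_data(ref, samplenum=HELDOUT_N, random_state=99)
    return {
        "ref": ref,
        "true_means": true_means,
        "model": model,
        "history": history,
        "train": train_set,
        "heldout": heldout,
    }


@pytest.fixture
def small_beta():
    rng = np.random.default_rng(0)
    values = rng.uniform(0, 1, size=(10, 4))
    return pd.DataFrame(
        values,
        index=pd.Index([f"cg{i:05d}" for i in range(10)], name="probe_id"),
        columns=[f"s{i}" for i in range(4)],
    )


def heldout_frame(ref: pd.DataFrame, heldout: sim.SimulatedSet) -> pd.DataFrame:
    """Held-out mixtures as a probe x sample frame aligned with the reference."""
    return pd.DataFrame(
        heldout.x.T,
        index=ref.index,
        columns=[f"mix_{i}" for i in range(heldout.x.shape[0])],
    )
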