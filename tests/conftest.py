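import numpy as np
import pytest

from sozdetect import (
    ModelSpec,
    PreprocessConfig,
    SyntheticSpec,
    TrainConfig,
    default_schedule,
    gen_multichannel,
    gen_uci_like,
    save_checkpoint,
)
from sozdetect.training import train_single


@pytest.fixture(scope="session")
def uci_small():
    """A small labelled-window table: 40 rows per class, fixed seed."""
    return gen_uci_like(40, SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def trained(tmp_path_factory):
    """One converged classifier shared by detection/localization/CLI tests.

    Trained once per session on 500 synthetic windows; also saved as a
    checkpoint archive for the CLI round trips.
    """
    ws = gen_uci_like(100, SyntheticSpec(seed=5))
    config = TrainConfig(seed=1)
    model_spec = ModelSpec()
    pp = PreprocessConfig()
    weights, history = train_single(ws, config, model_spec, pp)
    path = tmp_path_factory.mktemp("ckpt") / "checkpoint.npz"
    save_checkpoint(weights, model_spec, pp, path)
    return {
        "weights": weights,
        "model_spec": model_spec,
        "preprocess": pp,
        "history": history,
        "checkpoint_path": path,
        "train_set": ws,
    }


@pytest.fixture(scope="session")
def seizure_scenario():
    """A 21-channel recording with a right-frontal onset and its ground truth."""
    spec = SyntheticSpec(seed=9)
    schedule = default_schedule(onset_sites=("F8", "F4"))
    recording, truth = gen_multichannel(schedule, spec)
    return {"recording": recording, "truth": truth, "schedule": schedule,
            "spec": spec}
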