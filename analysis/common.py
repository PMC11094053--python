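"""Shared study configuration for the numbered analysis scripts.

All scripts regenerate the cohort deterministically from this one config, so
they can run independently; the trained network is cached under scratch/ by
02_split_and_train.py and reused by the later scripts when present.
"""

from pathlib import Path

import numpy as np

from cinefunc import model as mdl
from cinefunc.pipeline import (RunConfig, stage_generate, stage_observers,
                               stage_split, stage_train)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
MODEL_CACHE = SCRATCH / "model_state.npz"

STUDY = RunConfig(seed=0, out_dir=str(RESULTS / "study"))


def cohort():
    scans = stage_generate(STUDY)
    split = stage_split(STUDY, scans)
    labelings = stage_observers(STUDY, scans)
    return scans, split, labelings


def trained_model(scans, split, labelings):
    """Load the cached network, or train it and cache the weights."""
    net = mdl.SegNet(channels=STUDY.model_channels, input_size=STUDY.image_size,
                     normalization=STUDY.normalization)
    if MODEL_CACHE.exists():
        net.load_state_dict(dict(np.load(MODEL_CACHE)))
        return net, None
    net, records = stage_train(STUDY, scans, split, labelings)
    SCRATCH.mkdir(exist_ok=True)
    np.savez(MODEL_CACHE, **net.state_dict())
    return net, records
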