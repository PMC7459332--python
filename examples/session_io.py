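"""Write a session to the HDF5 container and read it back.

Shows the on-disk layout: array datasets plus a trials CSV sidecar, and a
lossless round-trip.
"""

import tempfile
from pathlib import Path

import numpy as np

from mlipop import io, synth
from mlipop.config import EnsembleConfig, LearningCurve, SessionConfig

session = synth.generate_session(SessionConfig(n_trials=20, seed=5),
                                 EnsembleConfig(), LearningCurve())

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "session.h5"
    io.save_session(session, path)
    loaded = io.load_session(path)
    print(f"container : {path.name} + {path.with_suffix('.trials.csv').name}")
    print(f"F matrix  : {loaded.F.shape} (frames x ROIs) at "
          f"{loaded.imaging_rate} Hz")
    print(f"licks     : {loaded.lick_times.size} events")
    print(f"round-trip exact: {np.array_equal(loaded.F, session.F)}")
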