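"""HDF5 session container and CSV table writers.

Layout: datasets /F, /dff, /licks, /velocity, /acceleration plus root
attributes (imaging_rate, lick_rate_hz, seed, version); the trial table
lives in a sidecar CSV next to the container. Aligned tensors are stored
under /aligned/<alignment>.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .dff import TrialTensor
from .session import Session, trials_from_dataframe

log = logging.getLogger(__name__)

FORMAT_VERSION = 1
REQUIRED = ("F", "licks")


def _trials_csv_path(path: Path) -> Path:
    return path.with_suffix(".trials.csv")


def save_session(session: Session, path: str | Path) -> Path:
    """Write a session container (HDF5) plus its trials CSV; returns path."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["version"] = FORMAT_VERSION
        f.attrs["imaging_rate"] = session.imaging_rate
        f.attrs["lick_rate_hz"] = session.lick_rate_hz
        if session.seed is not None:
            f.attrs["seed"] = session.seed
        f.attrs["meta"] = json.dumps(session.meta)
        f.create_dataset("F", data=session.F)
        f.create_dataset("licks", data=session.lick_times)
        if session.dff is not None:
            f.create_dataset("dff", data=session.dff)
        if session.body_velocity is not None:
            f.create_dataset("velocity", data=session.body_velocity)
        if session.body_acceleration is not None:
            f.create_dataset("acceleration", data=session.body_acceleration)
    # %.17g guarantees float round-trip through the text table
    session.trials_dataframe().to_csv(_trials_csv_path(path), index=False,
                                      float_format="%.17g")
    return path


def load_session(path: str | Path) -> Session:
    """Read a session container; raises naming any missing dataset."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        missing = [name for name in REQUIRED if name not in f]
        if missing:
            raise ValueError(f"session container missing datasets: {missing}")
        if "version" not in f.attrs:
            log.warning("session container has no version attribute; "
                        "attempting best-effort load")
        kwargs = dict(
            F=f["F"][()],
            lick_times=f["licks"][()],
            imaging_rate=float(f.attrs.get("imaging_rate", 5.3)),
            lick_rate_hz=float(f.attrs.get("lick_rate_hz", 100.0)),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            meta=json.loads(f.attrs.get("meta", "{}")),
        )
        for name, key in (("dff", "dff"), ("velocity", "body_velocity"),
                          ("acceleration", "body_acceleration")):
            if name in f:
                kwargs[key] = f[name][()]
    trials_csv = _trials_csv_path(path)
    if not trials_csv.exists():
        raise ValueError(f"missing trials table {trials_csv}")
    trials = trials_from_dataframe(
        pd.read_csv(trials_csv, float_precision="round_trip"))
    return Session(trials=trials, **kwargs)


def save_tensor(tensor: TrialTensor, path: str | Path) -> None:
    """Append an aligned trial tensor under /aligned/<alignment>."""
    with h5py.File(path, "a") as f:
        grp = f.require_group("aligned")
        if tensor.alignment in grp:
            del grp[tensor.alignment]
        g = grp.create_group(tensor.alignment)
        g.create_dataset("values", data=tensor.values)
        g.create_dataset("t_rel", data=tensor.t_rel)
        g.create_dataset("trial_indices", data=tensor.trial_indices)
        g.attrs["imaging_rate"] = tensor.imaging_rate


def load_tensor(path: str | Path, alignment: str) -> TrialTensor:
    with h5py.File(path, "r") as f:
        if "aligned" not in f or alignment not in f["aligned"]:
            raise ValueError(f"no aligned tensor {alignment!r} in {path}")
        g = f["aligned"][alignment]
        return TrialTensor(values=g["values"][()], t_rel=g["t_rel"][()],
                           alignment=alignment,
                           trial_indices=g["trial_indices"][()],
                           imaging_rate=float(g.attrs["imaging_rate"]))
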