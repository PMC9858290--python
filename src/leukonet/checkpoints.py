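"""Single-file HDF5 checkpoints: architecture spec + weights + provenance."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np


def save_checkpoint(path, kind: str, spec, state: dict[str, np.ndarray],
                    meta: dict | None = None) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = kind
        f.attrs["spec"] = json.dumps(dataclasses.asdict(spec))
        f.attrs["meta"] = json.dumps(meta or {})
        g = f.create_group("state")
        for key, arr in state.items():
            # flat keys: '/' would otherwise create nested HDF5 groups
            g.create_dataset(key.replace("/", "|"), data=np.asarray(arr))
    return path


def load_checkpoint(path) -> tuple[str, dict, dict[str, np.ndarray], dict]:
    path = Path(path)
    with h5py.File(path, "r") as f:
        kind = f.attrs["kind"]
        spec = json.loads(f.attrs["spec"])
        meta = json.loads(f.attrs["meta"])
        state = {k.replace("|", "/"): np.asarray(v) for k, v in f["state"].items()}
    return kind, spec, state, meta
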