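"""Self-describing model checkpoints (npz: config JSON + weights + seed)."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from cytomil.models.admil import ADMIL, MILConfig
from cytomil.models.tcs_cnn import TCSCNN, TCSCNNConfig


def _flatten_state(state, prefix: str, out: dict) -> None:
    if isinstance(state, dict):
        for k, v in state.items():
            _flatten_state(v, f"{prefix}/{k}", out)
    elif isinstance(state, list):
        for i, v in enumerate(state):
            _flatten_state(v, f"{prefix}/{i}", out)
    else:
        out[prefix] = state


def save_checkpoint(model: TCSCNN | ADMIL, path: str | Path, metadata: dict | None = None) -> None:
    if isinstance(model, ADMIL):
        kind = "admil"
        config = dataclasses.asdict(model.config)
    else:
        kind = "tcs_cnn"
        config = dataclasses.asdict(model.config)
    arrays: dict[str, np.ndarray] = {}
    _flatten_state(model.get_state(), "state", arrays)
    header = json.dumps({"kind": kind, "config": config, "metadata": metadata or {}})
    np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8), **arrays)


def _set_nested(container, keys: list[str], value) -> None:
    key = keys[0]
    if isinstance(container, list):
        key = int(key)
    if len(keys) == 1:
        container[key][...] = value
        return
    _set_nested(container[key], keys[1:], value)


def load_checkpoint(path: str | Path) -> TCSCNN | ADMIL:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        cfg = header["config"]
        if header["kind"] == "admil":
            cfg["backbone"]["conv_channels"] = tuple(cfg["backbone"]["conv_channels"])
            cfg["backbone"]["fc_sizes"] = tuple(cfg["backbone"]["fc_sizes"])
            cfg["backbone"] = TCSCNNConfig(**cfg["backbone"])
            model: TCSCNN | ADMIL = ADMIL(MILConfig(**cfg))
        else:
            cfg["conv_channels"] = tuple(cfg["conv_channels"])
            cfg["fc_sizes"] = tuple(cfg["fc_sizes"])
            model = TCSCNN(TCSCNNConfig(**cfg))
        state = model.get_state()
        for key in data.files:
            if key == "__header__":
                continue
            _set_nested(state, key.split("/")[1:], data[key])
        model.set_state(state)
    return model
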