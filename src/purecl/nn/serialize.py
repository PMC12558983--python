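"""Single-file parameter archives (NumPy ``.npz`` with a version tag)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .layers import Module

FORMAT_VERSION = 1

__all__ = ["save_checkpoint", "load_checkpoint", "read_checkpoint_meta"]


def read_checkpoint_meta(path) -> dict:
    """Read only the metadata block of a checkpoint."""
    with np.load(path) as archive:
        header = json.loads(archive["__header__"].tobytes().decode())
    return header.get("meta", {})


def save_checkpoint(path, module: Module, meta: dict | None = None) -> None:
    state = module.state_dict()
    header = {"format_version": FORMAT_VERSION, "meta": meta or {}}
    arrays = {f"param/{k}": v for k, v in state.items()}
    arrays["__header__"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path, module: Module) -> dict:
    """Load parameters into ``module`` in place; returns the metadata dict."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with np.load(path) as archive:
        header = json.loads(archive["__header__"].tobytes().decode())
        if header.get("format_version") != FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint version in {path}")
        state = {k[len("param/"):]: archive[k] for k in archive.files if k.startswith("param/")}
    module.load_state_dict(state)
    return header.get("meta", {})
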