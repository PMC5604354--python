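"""Checkpoint container: JSON manifest plus one array file per tensor.

A checkpoint is a directory holding ``manifest.json`` (architecture,
layer sizes, feature-layout version, training configuration, tensor
names) and one ``.npy`` file per parameter tensor.  Round trips are
bit-exact, which the test suite enforces.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .nn import DenseParams
from .recurrent import RecurrentParams

__all__ = ["save_checkpoint", "load_checkpoint"]


def _dense_tensor_map(p: DenseParams) -> dict[str, np.ndarray]:
    out = {}
    for i, (w, b) in enumerate(zip(p.weights, p.biases)):
        out[f"W{i}"] = w
        out[f"b{i}"] = b
    return out


def save_checkpoint(path, params, meta: dict) -> None:
    """Write params (DenseParams or RecurrentParams) under ``path``.

    ``meta`` must be JSON-serializable; the architecture kind is recorded
    automatically.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if isinstance(params, RecurrentParams):
        tensors = {"W_in": params.W_in, "U_rec": params.U_rec, "b_h": params.b_h}
        tensors.update({f"head_{k}": v for k, v in _dense_tensor_map(params.head).items()})
        kind = "recurrent"
        extra = {"memory_length": params.memory_length,
                 "n_head_layers": len(params.head.weights)}
    elif isinstance(params, DenseParams):
        tensors = _dense_tensor_map(params)
        kind = "dense"
        extra = {"n_layers": len(params.weights)}
    else:
        raise TypeError(f"unsupported parameter container {type(params)!r}")
    manifest = {"kind": kind, "tensors": sorted(tensors), **extra, "meta": meta}
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    for name, arr in tensors.items():
        np.save(path / f"{name}.npy", arr)


def load_checkpoint(path):
    """Load a checkpoint; returns (params, meta)."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    arrays = {name: np.load(path / f"{name}.npy") for name in manifest["tensors"]}
    if manifest["kind"] == "dense":
        n = manifest["n_layers"]
        params = DenseParams([arrays[f"W{i}"] for i in range(n)],
                             [arrays[f"b{i}"] for i in range(n)])
    elif manifest["kind"] == "recurrent":
        n = manifest["n_head_layers"]
        head = DenseParams([arrays[f"head_W{i}"] for i in range(n)],
                           [arrays[f"head_b{i}"] for i in range(n)])
        params = RecurrentParams(arrays["W_in"], arrays["U_rec"], arrays["b_h"],
                                 head, manifest["memory_length"])
    else:
        raise ValueError(f"unknown checkpoint kind {manifest['kind']!r}")
    return params, manifest["meta"]
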