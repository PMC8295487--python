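"""JSON configuration schema for model specifications.

A config file is a single JSON object:

.. code-block:: json

    {
      "domain": {"a": -20.0, "b": 20.0},
      "h": 0.8,
      "alpha": null,
      "layers": {"L": 1, "sizes": [200]},
      "kernel": {"preset": "gauss_diff_sec35"},
      "activation": {"family": "heaviside", "theta": 1.0, "v0": 0.0},
      "stimulus": {"nu": -0.5, "u": "zero"},
      "initial": -1.5,
      "steps": 100
    }

``layers`` may instead be ``{"one_neuron_per_layer": true, "L": 200}`` for
the stacked-chain architecture.  ``kernel`` accepts either a ``preset``
name, explicit kernel parameters (``family`` plus the family's fields), or
— for one-neuron-per-layer chains — direct numeric weights
``{"values": {"intra": w0, "up": w1, "down": w2}}`` bypassing the spatial
kernel.  ``initial`` is a scalar (uniform field) or a nested list of
per-layer vectors.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .activations import ActivationSpec
from .dynamics import FieldState, ModelSpec, StimulusSpec
from .exceptions import ConfigurationError
from .kernels import (
    KERNEL_PRESETS,
    ConnectivityTensor,
    KernelSpec,
    build_connectivity,
)
from .model import DiscretizationParams, LayerArchitecture

__all__ = ["load_config", "model_from_config", "initial_state_from_config"]


def load_config(path: str | Path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"{path}: invalid JSON ({exc})") from exc


def _kernel_from_config(cfg: dict) -> KernelSpec | None:
    if "preset" in cfg:
        name = cfg["preset"]
        if name not in KERNEL_PRESETS:
            raise ConfigurationError(
                f"unknown kernel preset {name!r}; available: {sorted(KERNEL_PRESETS)}"
            )
        return KERNEL_PRESETS[name]
    if "values" in cfg:
        return None  # direct numeric weights, handled by the caller
    return KernelSpec(**cfg)


def _chain_connectivity(arch: LayerArchitecture, values: dict) -> ConnectivityTensor:
    """Constant intra/up/down weights on a one-neuron-per-layer chain."""
    if any(m != 1 for m in arch.sizes):
        raise ConfigurationError(
            "direct kernel values require the one-neuron-per-layer architecture"
        )
    intra = float(values.get("intra", 0.0))
    up = float(values.get("up", 0.0))  # weight from layer k+1 onto k
    down = float(values.get("down", 0.0))  # weight from layer k-1 onto k
    blocks = {}
    L = arch.n_layers
    for k in range(L):
        for l in range(L):
            if l not in arch.neighbors(k):
                w = None
            elif l == k:
                w = intra
            elif l == k + 1:
                w = up
            else:
                w = down
            blocks[(k, l)] = np.array([[w]]) if w is not None else np.zeros((1, 1))
    return ConnectivityTensor(layer_sizes=tuple(arch.sizes), blocks=blocks)


def model_from_config(cfg: dict) -> ModelSpec:
    try:
        dom = cfg["domain"]
        disc = DiscretizationParams(
            h=float(cfg["h"]),
            a=float(dom["a"]),
            b=float(dom["b"]),
            alpha_override=cfg.get("alpha"),
        )
        layers = cfg["layers"]
        if layers.get("one_neuron_per_layer"):
            arch = LayerArchitecture.layered_line(disc, int(layers["L"]))
        else:
            L = int(layers["L"])
            sizes = layers.get("sizes")
            if sizes is None:
                raise ConfigurationError("layers.sizes is required")
            if len(sizes) == 1 and L > 1:
                sizes = sizes * L
            if len(sizes) != L:
                raise ConfigurationError(
                    f"layers.sizes has {len(sizes)} entries for L={L}"
                )
            from .model import make_grid

            arch = LayerArchitecture(
                sizes=tuple(int(m) for m in sizes),
                positions=tuple(make_grid(disc, int(m)) for m in sizes),
            )
        kernel_cfg = cfg["kernel"]
        kspec = _kernel_from_config(kernel_cfg)
        if kspec is None:
            connectivity = _chain_connectivity(arch, kernel_cfg["values"])
        else:
            connectivity = build_connectivity(arch, kspec)
        act = cfg["activation"]
        activation = ActivationSpec(
            family=act["family"],
            theta=float(act.get("theta", 1.0)),
            v0=float(act.get("v0", 0.0)),
        )
        stim = cfg.get("stimulus", {})
        form = stim.get("u", "zero")
        values = None
        if form == "explicit":
            values = tuple(np.asarray(v, dtype=float) for v in stim["values"])
        stimulus = StimulusSpec(
            nu=float(stim.get("nu", 0.0)), form=form, values=values
        )
    except KeyError as exc:
        raise ConfigurationError(f"missing config key: {exc}") from exc
    return ModelSpec(
        architecture=arch,
        discretization=disc,
        connectivity=connectivity,
        activation=activation,
        stimulus=stimulus,
    )


def initial_state_from_config(cfg: dict, model: ModelSpec) -> FieldState:
    initial = cfg.get("initial", 0.0)
    if np.isscalar(initial):
        return model.uniform_state(float(initial))
    arch = model.architecture
    V = np.zeros((arch.n_layers, arch.max_size))
    if len(initial) != arch.n_layers:
        raise ConfigurationError(
            f"initial field has {len(initial)} layers, model has {arch.n_layers}"
        )
    for k, layer_vals in enumerate(initial):
        vals = np.asarray(layer_vals, dtype=float)
        if vals.shape != (arch.sizes[k],):
            raise ConfigurationError(
                f"initial field layer {k}: shape {vals.shape}, "
                f"expected ({arch.sizes[k]},)"
            )
        V[k, : arch.sizes[k]] = vals
    return FieldState(V=V)
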