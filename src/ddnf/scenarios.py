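"""Canned simulation scenarios on the standard configuration.

All scenarios share the domain Omega = [-20, 20], time step h = 0.8,
N = 100 steps, the excitation/inhibition difference-of-Gaussians kernel
(amplitudes 4.0 / 1.5, widths 1.0 / 4.5), resting level nu = -0.5 and the
uniform initial field V_0 = -1.5.  They differ in gain, input, and layout:

========  =======================================================
fig5      single layer (M = 200), hard threshold, no input
fig6      single layer, sigmoid, no input
fig7      single layer, hard threshold, Gaussian input bump
fig8      single layer, sigmoid, Gaussian input bump
fig9      200 single-neuron layers, sigmoid, no input
fig10     200 single-neuron layers, sigmoid, Gaussian input bump
fig11     single layer, sigmoid, Gaussian input; sweep of the
          memory factor alpha over 50 values in (0, 1]
========  =======================================================

The steepness and threshold of the sigmoid default to theta = 1, v0 = 0;
the probe index for the per-neuron panels maps the quoted probe coordinate
to the nearest grid point and is freely configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .activations import ActivationSpec
from .dynamics import (
    FieldState,
    ModelSpec,
    StimulusSpec,
    Trajectory,
    cobweb,
    simulate,
)
from .exceptions import ConfigurationError, ThresholdSingularityError
from .io import (
    write_cobweb_csv,
    write_manifest,
    write_report_json,
    write_trajectory_csv,
)
from .kernels import KERNEL_PRESETS, build_connectivity
from .model import DiscretizationParams, LayerArchitecture
from .stability import stability_report

__all__ = ["ScenarioSpec", "scenario", "run_scenario", "SCENARIO_NAMES"]

SCENARIO_NAMES = ("fig5", "fig6", "fig7", "fig8", "fig9", "fig10", "fig11")

_BASE = dict(h=0.8, a=-20.0, b=20.0, m=200, n_steps=100, nu=-0.5, v_init=-1.5)
#: convergence declared when one step moves the field by less than this
CONVERGENCE_TOL = 1e-6


@dataclass(frozen=True)
class ScenarioSpec:
    """A resolved scenario: model, horizon, initial value, probe, sweep grid."""

    name: str
    model: ModelSpec
    n_steps: int
    v_init: float
    probe: tuple[int, int]  # (layer, neuron), 0-based
    alphas: np.ndarray | None = None  # memory-factor sweep (fig11 only)


def _single_layer_model(
    activation: ActivationSpec, form: str, alpha_override: float | None = None
) -> ModelSpec:
    disc = DiscretizationParams(
        h=_BASE["h"], a=_BASE["a"], b=_BASE["b"], alpha_override=alpha_override
    )
    arch = LayerArchitecture.uniform(disc, 1, _BASE["m"])
    return ModelSpec(
        architecture=arch,
        discretization=disc,
        connectivity=build_connectivity(arch, KERNEL_PRESETS["gauss_diff_sec35"]),
        activation=activation,
        stimulus=StimulusSpec(nu=_BASE["nu"], form=form),
    )


def _layered_model(activation: ActivationSpec, form: str, n_layers: int) -> ModelSpec:
    disc = DiscretizationParams(h=_BASE["h"], a=_BASE["a"], b=_BASE["b"])
    arch = LayerArchitecture.layered_line(disc, n_layers)
    return ModelSpec(
        architecture=arch,
        discretization=disc,
        connectivity=build_connectivity(arch, KERNEL_PRESETS["gauss_diff_sec35"]),
        activation=activation,
        stimulus=StimulusSpec(nu=_BASE["nu"], form=form),
    )


def _nearest_index(model: ModelSpec, layer: int, x: float) -> int:
    return int(np.argmin(np.abs(model.architecture.positions[layer] - x)))


def scenario(
    name: str,
    theta: float = 1.0,
    v0: float = 0.0,
    n_layers: int = 200,
    probe: tuple[int, int] | None = None,
) -> ScenarioSpec:
    """Build one of the named scenarios with optional overrides."""
    if name not in SCENARIO_NAMES:
        raise ConfigurationError(
            f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}"
        )
    sigmoid = ActivationSpec(family="sigmoid", theta=theta, v0=v0)
    heaviside = ActivationSpec(family="heaviside", v0=v0)
    alphas = None
    if name == "fig5":
        model = _single_layer_model(heaviside, "zero")
        default_probe = (0, _BASE["m"] // 2)
    elif name == "fig6":
        model = _single_layer_model(sigmoid, "zero")
        default_probe = (0, _nearest_index(_single_layer_model(sigmoid, "zero"), 0, 9.548))
    elif name == "fig7":
        model = _single_layer_model(heaviside, "gaussian_space")
        default_probe = (0, _nearest_index(model, 0, 2.111))
    elif name == "fig8":
        model = _single_layer_model(sigmoid, "gaussian_space")
        default_probe = (0, _nearest_index(model, 0, -18.79))
    elif name == "fig9":
        model = _layered_model(sigmoid, "zero", n_layers)
        default_probe = (n_layers // 2, 0)
    elif name == "fig10":
        model = _layered_model(sigmoid, "gaussian_space", n_layers)
        default_probe = (n_layers // 2, 0)
    else:  # fig11: alpha sweep on the fig8 configuration
        model = _single_layer_model(sigmoid, "gaussian_space")
        default_probe = (0, _BASE["m"] // 2)
        alphas = np.arange(1, 51) / 50.0  # 50 even values in (0, 1], incl. 1
    return ScenarioSpec(
        name=name,
        model=model,
        n_steps=_BASE["n_steps"],
        v_init=_BASE["v_init"],
        probe=probe if probe is not None else default_probe,
        alphas=alphas,
    )


def _convergence_step(traj: Trajectory, tol: float = CONVERGENCE_TOL) -> int | None:
    diffs = np.max(np.abs(np.diff(traj.values, axis=0)), axis=(1, 2))
    hits = np.nonzero(diffs < tol)[0]
    return int(hits[0] + 1) if hits.size else None


def _field_summary(model: ModelSpec, V: np.ndarray) -> dict:
    arch = model.architecture
    vals = np.concatenate([V[k, :m] for k, m in enumerate(arch.sizes)])
    # spatial profile along the first layer (or along the layer chain)
    if arch.n_layers == 1:
        profile = V[0, : arch.sizes[0]]
        coords = model.architecture.positions[0]
    else:
        profile = np.array([V[k, 0] for k in range(arch.n_layers)])
        coords = np.array([model.architecture.positions[k][0] for k in range(arch.n_layers)])
    sign_changes = int(np.sum(np.diff(np.sign(profile)) != 0))
    return {
        "min": float(vals.min()),
        "max": float(vals.max()),
        "mean": float(vals.mean()),
        "spread": float(vals.max() - vals.min()),
        "argmax_coordinate": float(coords[int(np.argmax(profile))]),
        "sign_changes": sign_changes,
    }


def _run_alpha_sweep(spec: ScenarioSpec, out_dir: Path) -> tuple[dict, list[Path]]:
    """fig11: final field V_N(x) for each memory factor alpha in the sweep."""
    import csv as _csv

    from .io import trajectory_header

    rows = []
    for alpha in spec.alphas:
        disc = spec.model.discretization
        model = ModelSpec(
            architecture=spec.model.architecture,
            discretization=DiscretizationParams(
                h=disc.h, a=disc.a, b=disc.b, alpha_override=float(alpha)
            ),
            connectivity=spec.model.connectivity,
            activation=spec.model.activation,
            stimulus=spec.model.stimulus,
        )
        traj = simulate(model, model.uniform_state(spec.v_init), spec.n_steps)
        rows.append((float(alpha), traj.final().V))
    path = out_dir / "alpha_sweep.csv"
    sizes = spec.model.architecture.sizes
    with path.open("w", newline="") as fh:
        writer = _csv.writer(fh)
        writer.writerow(["alpha"] + trajectory_header(sizes)[1:])
        for alpha, V in rows:
            flat = []
            for k, m in enumerate(sizes):
                flat.extend(repr(float(v)) for v in V[k, :m])
            writer.writerow([repr(alpha)] + flat)
    v0_field = spec.model.uniform_state(spec.v_init).V
    frozen = rows[-1][1]  # alpha = 1 is the last sweep value
    summary = {
        "alphas": [a for a, _ in rows],
        "alpha_one_equals_initial": bool(np.array_equal(frozen, v0_field)),
        "final_field": _field_summary(spec.model, rows[-2][1]),
    }
    return summary, [path]


def run_scenario(spec: ScenarioSpec, out_dir: str | Path) -> dict:
    """Run a scenario and write trajectory, report, cobweb, summary, manifest.

    Returns the summary dictionary (also written as ``summary.json``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    summary: dict = {"name": spec.name, "n_steps": spec.n_steps}

    if spec.alphas is not None:
        sweep_summary, files = _run_alpha_sweep(spec, out_dir)
        summary.update(sweep_summary)
    else:
        model = spec.model
        traj = simulate(model, model.uniform_state(spec.v_init), spec.n_steps)
        files.append(write_trajectory_csv(traj, out_dir / "trajectory.csv"))
        files.append(
            write_cobweb_csv(cobweb(traj, *spec.probe), out_dir / "cobweb.csv")
        )
        summary["probe"] = {"layer": spec.probe[0] + 1, "neuron": spec.probe[1] + 1}
        summary["final_field"] = _field_summary(model, traj.final().V)
        summary["convergence_step"] = _convergence_step(traj)
        try:
            report = stability_report(model, traj.final())
            files.append(write_report_json(report, out_dir / "stability.json"))
            summary["stability"] = {
                "rho": report.rho,
                "classification": report.classification,
            }
        except ThresholdSingularityError:
            summary["stability"] = {
                "classification": "unavailable",
                "reason": "final field touches the emission threshold",
            }

    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    files.append(summary_path)
    write_manifest(out_dir, files)
    return summary
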