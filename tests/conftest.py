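import numpy as np
import pytest

from ddnf import (
    ActivationSpec,
    DiscretizationParams,
    FieldState,
    KernelSpec,
    LayerArchitecture,
    ModelSpec,
    StimulusSpec,
    build_connectivity,
    ddnf_step,
)
from ddnf.kernels import KERNEL_PRESETS


@pytest.fixture
def sec35_disc() -> DiscretizationParams:
    """The standard discretization: Omega = [-20, 20], h = 0.8."""
    return DiscretizationParams(h=0.8, a=-20.0, b=20.0)


@pytest.fixture
def sec35_heaviside_model(sec35_disc) -> ModelSpec:
    """Single layer, M = 200, lateral-inhibition kernel, hard threshold, no input."""
    arch = LayerArchitecture.uniform(sec35_disc, 1, 200)
    return ModelSpec(
        architecture=arch,
        discretization=sec35_disc,
        connectivity=build_connectivity(arch, KERNEL_PRESETS["gauss_diff_sec35"]),
        activation=ActivationSpec(family="heaviside", v0=0.0),
        stimulus=StimulusSpec(nu=-0.5, form="zero"),
    )


@pytest.fixture
def sec35_sigmoid_model(sec35_disc) -> ModelSpec:
    arch = LayerArchitecture.uniform(sec35_disc, 1, 200)
    return ModelSpec(
        architecture=arch,
        discretization=sec35_disc,
        connectivity=build_connectivity(arch, KERNEL_PRESETS["gauss_diff_sec35"]),
        activation=ActivationSpec(family="sigmoid", theta=1.0, v0=0.0),
        stimulus=StimulusSpec(nu=-0.5, form="zero"),
    )


def small_model(
    seed: int,
    n_layers: int = 1,
    max_size: int = 5,
    activation: str = "sigmoid",
) -> ModelSpec:
    """Random small model for oracle comparisons; deterministic in the seed."""
    rng = np.random.default_rng(seed)
    disc = DiscretizationParams(h=float(rng.uniform(0.2, 1.5)), a=-1.0, b=1.0)
    sizes = tuple(int(m) for m in rng.integers(1, max_size + 1, size=n_layers))
    positions = tuple(np.sort(rng.uniform(-1.0, 1.0, size=m)) for m in sizes)
    arch = LayerArchitecture(sizes=sizes, positions=positions)
    kernel = KernelSpec(family="gaussian", sigma=float(rng.uniform(0.3, 1.5)))
    theta = float(rng.uniform(0.5, 3.0))
    return ModelSpec(
        architecture=arch,
        discretization=disc,
        connectivity=build_connectivity(arch, kernel),
        activation=ActivationSpec(family=activation, theta=theta),
        stimulus=StimulusSpec(nu=float(rng.uniform(-0.5, 0.0)), form="zero"),
    )


def finite_difference_jacobian(
    model: ModelSpec, v_star: FieldState, eps: float = 1e-6
) -> np.ndarray:
    """Central-difference Jacobian of one update step, stacked in layer order.

    Independent oracle for the analytic Jacobian: perturbs every valid field
    entry in turn and differences the full step map.
    """
    arch = model.architecture
    total = arch.total_size
    J = np.zeros((total, total))
    offsets = np.concatenate([[0], np.cumsum(arch.sizes)])

    def flat(V: np.ndarray) -> np.ndarray:
        return np.concatenate([V[k, : arch.sizes[k]] for k in range(arch.n_layers)])

    col = 0
    for l in range(arch.n_layers):
        for j in range(arch.sizes[l]):
            Vp = v_star.V.copy()
            Vm = v_star.V.copy()
            Vp[l, j] += eps
            Vm[l, j] -= eps
            fp = flat(ddnf_step(FieldState(V=Vp), model).V)
            fm = flat(ddnf_step(FieldState(V=Vm), model).V)
            J[:, col] = (fp - fm) / (2.0 * eps)
            col += 1
    assert col == total and offsets[-1] == total
    return J
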