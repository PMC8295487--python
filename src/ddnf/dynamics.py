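"""The discrete neural-field update rule and its fixed-point machinery.

One time step of the layered lattice field reads, entrywise,

    V_{i,n+1}^(k) = alpha V_{i,n}^(k)
                    + (1 - alpha) sum_{l in L_k} sum_j beta_l W_ij^(k,l) G(V_{j,n}^(l))
                    + (1 - alpha) S_i^(k),

with memory factor alpha = exp(-h), Riemann weights beta_l = |Omega|/M_l,
layer-neighbor sets L_k, gain G, and stimulus S = nu + U (resting level nu
plus external input U).  The step is exactly the averaged (Mann-type)
iteration V_{n+1} = alpha V_n + (1 - alpha) T(V_n) for the interaction map
T(V) = Gamma G(V) + S, so simulating the field and solving its fixed-point
condition V = T(V) are the same loop; :func:`mann_iterate` just adds
residual tracking and the contraction diagnostic C W0 |Omega| built from the
gain's Lipschitz constant C and the weight bound W0.

For a hard-threshold gain with no external input and an everywhere
sub-threshold field, the coupling term vanishes identically and the
trajectory has the closed form alpha^n V_0 + nu (1 - alpha^n), relaxing
geometrically to the resting level (:func:`heaviside_closed_form`), with the
a-priori envelope of :func:`trajectory_bound` valid for any bounded weights
and stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .activations import ActivationSpec, evaluate_activation, lipschitz_constant
from .exceptions import ConfigurationError, InputError, NotLipschitzError
from .kernels import ConnectivityTensor, kernel_bound
from .model import DiscretizationParams, LayerArchitecture, make_grid  # noqa: F401 (re-export)

__all__ = [
    "StimulusSpec",
    "ModelSpec",
    "FieldState",
    "Trajectory",
    "MannResult",
    "make_grid",
    "ddnf_step",
    "simulate",
    "heaviside_closed_form",
    "trajectory_bound",
    "mann_iterate",
    "fixed_point_residual",
    "cobweb",
]


@dataclass(frozen=True)
class StimulusSpec:
    """Time-constant stimulus S = nu + U.

    ``nu`` is the resting level (typically negative: with no external input
    the field settles below threshold and emits nothing).  ``form`` selects
    the external input U:

    * ``"zero"``: U = 0 everywhere;
    * ``"gaussian_space"``: U(x) = (2 pi)^(-1/2) exp(-x^2 / 2), a standard
      normal bump centered on the domain origin;
    * ``"explicit"``: per-layer input vectors supplied in ``values``.
    """

    nu: float = 0.0
    form: str = "zero"
    values: tuple[np.ndarray, ...] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.form not in ("zero", "gaussian_space", "explicit"):
            raise ConfigurationError(f"unknown stimulus form {self.form!r}")
        if not np.isfinite(self.nu):
            raise ConfigurationError("resting level nu must be finite")
        if self.form == "explicit" and self.values is None:
            raise ConfigurationError("explicit stimulus requires values")

    def build(self, arch: LayerArchitecture) -> np.ndarray:
        """Padded (L, M) stimulus matrix; padded entries are zero."""
        L, M = arch.n_layers, arch.max_size
        S = np.zeros((L, M))
        for k in range(L):
            m = arch.sizes[k]
            if self.form == "zero":
                u = 0.0
            elif self.form == "gaussian_space":
                x = arch.positions[k]
                u = np.exp(-0.5 * x**2) / np.sqrt(2.0 * np.pi)
            else:
                u = np.asarray(self.values[k], dtype=float)
                if u.shape != (m,):
                    raise ConfigurationError(
                        f"explicit stimulus for layer {k} has shape {u.shape}, "
                        f"expected ({m},)"
                    )
            S[k, :m] = self.nu + u
        return S


@dataclass(frozen=True)
class ModelSpec:
    """A fully specified lattice neural field."""

    architecture: LayerArchitecture
    discretization: DiscretizationParams
    connectivity: ConnectivityTensor
    activation: ActivationSpec
    stimulus: StimulusSpec

    def __post_init__(self) -> None:
        if self.connectivity.layer_sizes != tuple(self.architecture.sizes):
            raise ConfigurationError(
                f"connectivity layer sizes {self.connectivity.layer_sizes} do not "
                f"match architecture sizes {tuple(self.architecture.sizes)}"
            )

    def stimulus_matrix(self) -> np.ndarray:
        return self.stimulus.build(self.architecture)

    def uniform_state(self, value: float, n: int = 0) -> "FieldState":
        """Constant field ``value`` on every neuron (padding kept at zero)."""
        arch = self.architecture
        V = np.zeros((arch.n_layers, arch.max_size))
        for k, m in enumerate(arch.sizes):
            V[k, :m] = value
        return FieldState(V=V, n=n)


@dataclass(frozen=True)
class FieldState:
    """Padded L x M potential matrix at time index n.

    Row k holds layer k; entries beyond that layer's size are zero padding
    and stay zero under iteration.
    """

    V: np.ndarray
    n: int = 0

    def __post_init__(self) -> None:
        if self.V.ndim != 2:
            raise InputError(f"field matrix must be 2-D, got shape {self.V.shape}")
        if not np.all(np.isfinite(self.V)):
            raise InputError("field state contains non-finite entries")


class Trajectory:
    """Time course of field states n = 0..N, stored as an (N+1, L, M) array."""

    def __init__(self, values: np.ndarray, sizes: tuple[int, ...]):
        if values.ndim != 3:
            raise InputError("trajectory array must have shape (N+1, L, M)")
        self.values = values
        self.sizes = tuple(sizes)

    @property
    def n_steps(self) -> int:
        return self.values.shape[0] - 1

    def __len__(self) -> int:
        return self.values.shape[0]

    def __getitem__(self, n: int) -> FieldState:
        return FieldState(V=self.values[n], n=n)

    def __iter__(self) -> Iterator[FieldState]:
        for n in range(len(self)):
            yield self[n]

    def probe(self, layer: int, i: int) -> np.ndarray:
        """Time series V_n of one neuron (0-based layer and index)."""
        L, M = self.values.shape[1:]
        if not (0 <= layer < L and 0 <= i < self.sizes[layer]):
            raise InputError(f"probe index (layer={layer}, i={i}) out of range")
        return self.values[:, layer, i]

    def final(self) -> FieldState:
        return self[self.n_steps]


@dataclass
class MannResult:
    """Outcome of the averaged fixed-point iteration."""

    fixed_point: FieldState
    residuals: np.ndarray
    converged: bool
    iterations: int
    tol: float
    contraction_product: float | None
    convergence_guaranteed: bool


def _coupling(model: ModelSpec, V: np.ndarray) -> np.ndarray:
    """Interaction term sum_{l in L_k} beta_l W^(k,l) G(V^(l)), padded (L, M)."""
    arch = model.architecture
    disc = model.discretization
    out = np.zeros_like(V)
    gains = [
        evaluate_activation(model.activation, V[l, : arch.sizes[l]])
        for l in range(arch.n_layers)
    ]
    for k in range(arch.n_layers):
        acc = np.zeros(arch.sizes[k])
        for l in arch.neighbors(k):
            acc += disc.beta(arch.sizes[l]) * (
                model.connectivity.block(k, l) @ np.atleast_1d(gains[l])
            )
        out[k, : arch.sizes[k]] = acc
    return out


def interaction_map(model: ModelSpec, V: np.ndarray) -> np.ndarray:
    """T(V) = Gamma G(V) + S, the map whose fixed points are field equilibria."""
    return _coupling(model, V) + model.stimulus_matrix()


def ddnf_step(state: FieldState, model: ModelSpec) -> FieldState:
    """Advance the field one time step: V <- alpha V + (1 - alpha) T(V)."""
    arch = model.architecture
    expected = (arch.n_layers, arch.max_size)
    if state.V.shape != expected:
        raise InputError(
            f"field shape {state.V.shape} does not match model shape {expected}"
        )
    alpha = model.discretization.alpha
    V_new = alpha * state.V + (1.0 - alpha) * interaction_map(model, state.V)
    # re-zero the padding: alpha*0 + (1-alpha)*0 is exact, but keep it explicit
    for k, m in enumerate(arch.sizes):
        V_new[k, m:] = 0.0
    if not np.all(np.isfinite(V_new)):
        raise OverflowError(f"field overflowed at time index {state.n + 1}")
    return FieldState(V=V_new, n=state.n + 1)


def simulate(model: ModelSpec, V0: FieldState, n_steps: int) -> Trajectory:
    """Iterate the update rule ``n_steps`` times from ``V0``.

    Deterministic: identical inputs give bit-identical trajectories.
    """
    if n_steps < 0:
        raise InputError(f"n_steps must be >= 0, got {n_steps}")
    arch = model.architecture
    values = np.empty((n_steps + 1, arch.n_layers, arch.max_size))
    values[0] = V0.V
    state = FieldState(V=V0.V, n=V0.n)
    for n in range(n_steps):
        try:
            state = ddnf_step(state, model)
        except OverflowError as exc:  # re-raise with the absolute time index
            raise OverflowError(f"{exc} (step {n + 1} of {n_steps})") from None
        values[n + 1] = state.V
    return Trajectory(values=values, sizes=tuple(arch.sizes))


def heaviside_closed_form(
    v0_entry: float, params: DiscretizationParams, nu: float, n: int
) -> float:
    """Closed-form potential alpha^n V_0 + nu (1 - alpha^n) after n steps.

    Valid for a hard-threshold gain with zero external input on a trajectory
    that stays strictly below the threshold: the emission term is then
    identically zero and each step contributes Y = (1 - alpha) nu, whose
    geometric partial sum is nu (1 - alpha^n).  The caller is responsible for
    the sub-threshold hypothesis.
    """
    if n < 0:
        raise InputError(f"time index must be >= 0, got {n}")
    alpha_n = params.alpha**n
    return alpha_n * v0_entry + nu * (1.0 - alpha_n)


def trajectory_bound(model: ModelSpec, V0: FieldState, n: int) -> float:
    """A-priori envelope alpha^n max|V_0| + Y_m (1 - alpha^(n+1)) / (1 - alpha).

    Here Y_m = (1 - alpha)(S_bar + |Omega| W_bar) with S_bar the stimulus
    bound and W_bar the weight bound: each step's innovation is at most Y_m
    because the gain is bounded by 1 and the Riemann weights of one layer sum
    to |Omega|.  Every hard-threshold trajectory obeys |V_{i,n}| <= bound.
    """
    if n < 0:
        raise InputError(f"time index must be >= 0, got {n}")
    disc = model.discretization
    alpha = disc.alpha
    s_bar = float(np.max(np.abs(model.stimulus_matrix())))
    w_bar = kernel_bound(model.connectivity)
    y_m = (1.0 - alpha) * (s_bar + disc.omega * w_bar)
    v0_max = float(np.max(np.abs(V0.V)))
    if alpha == 1.0:
        return v0_max  # frozen field: Y_m = 0 and the state never moves
    return alpha**n * v0_max + y_m * (1.0 - alpha ** (n + 1)) / (1.0 - alpha)


def fixed_point_residual(V: FieldState, model: ModelSpec) -> float:
    """Sup-norm violation ||V - T(V)||_inf of the equilibrium condition."""
    T = interaction_map(model, V.V)
    arch = model.architecture
    best = 0.0
    for k, m in enumerate(arch.sizes):
        best = max(best, float(np.max(np.abs(V.V[k, :m] - T[k, :m]))))
    return best


def mann_iterate(
    model: ModelSpec,
    V0: FieldState,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> MannResult:
    """Averaged fixed-point iteration V <- alpha V + (1 - alpha) T(V).

    Stops when the sup-norm update ||V_{n+1} - V_n||_inf drops below ``tol``.
    The contraction diagnostic is C W0 |Omega| (gain Lipschitz constant C
    times weight bound W0 times domain size); when it does not exceed 1 the
    interaction map is nonexpansive and convergence of the averaged scheme is
    guaranteed.  For a hard-threshold gain no Lipschitz constant exists and
    the diagnostic is reported as unavailable.

    Exhausting ``max_iter`` returns a non-converged result (no exception).
    """
    if not tol > 0:
        raise InputError(f"tol must be positive, got {tol}")
    try:
        c = lipschitz_constant(model.activation)
        product = c * kernel_bound(model.connectivity) * model.discretization.omega
        guaranteed = product <= 1.0
    except NotLipschitzError:
        product = None
        guaranteed = False

    state = FieldState(V=V0.V, n=V0.n)
    residuals: list[float] = []
    converged = False
    its = 0
    for its in range(1, max_iter + 1):
        new = ddnf_step(state, model)
        res = float(np.max(np.abs(new.V - state.V)))
        residuals.append(res)
        state = new
        if res < tol:
            converged = True
            break
    return MannResult(
        fixed_point=state,
        residuals=np.array(residuals),
        converged=converged,
        iterations=its,
        tol=tol,
        contraction_product=product,
        convergence_guaranteed=guaranteed,
    )


def cobweb(traj: Trajectory, layer: int, i: int) -> list[tuple[float, float]]:
    """Cobweb polyline [(V_n, V_n), (V_n, V_{n+1})] for one neuron's orbit.

    The staircase drawn between the diagonal and the one-step return map;
    arrows that settle indicate convergence, closed loops indicate
    oscillation.
    """
    series = traj.probe(layer, i)
    pairs: list[tuple[float, float]] = []
    for n in range(len(series) - 1):
        pairs.append((float(series[n]), float(series[n])))
        pairs.append((float(series[n]), float(series[n + 1])))
    return pairs
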