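"""Seeded random model generator for tests and experiments.

Models are drawn from explicit parameter ranges with a
``numpy.random.default_rng`` stream, so an identical seed reproduces the
model bit-exactly.  Two regime targets are supported for single-layer
models:

* ``stable``: weights are rescaled so the row criterion max_i |mu_i| at the
  zero field stays below 0.9, guaranteeing a contracting linearization;
* ``unstable``: an equilibrium is planted by construction (the stimulus is
  set to S = V* - Gamma G(V*), making an arbitrary chosen V* an exact fixed
  point) and the weights are scaled until the spectral radius of the
  Jacobian at V* exceeds the requested level.

``fixture_with_fixed_point`` exposes the planted-equilibrium construction
directly, returning the model together with its exact fixed point — the
natural ground truth for stability-versus-dynamics checks, since generic
models admit no closed-form equilibria.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activations import ActivationSpec, evaluate_activation
from .dynamics import FieldState, ModelSpec, StimulusSpec, interaction_map
from .exceptions import ConfigurationError
from .kernels import ConnectivityTensor, KernelSpec, build_connectivity
from .model import DiscretizationParams, LayerArchitecture
from .stability import build_jacobian, mu_single_layer

__all__ = ["FixtureSpec", "generate_fixture", "fixture_with_fixed_point"]


@dataclass(frozen=True)
class FixtureSpec:
    """Ranges for the random model draw.

    ``regime`` is one of ``unconstrained``, ``stable``, ``unstable``
    (the latter two are single-layer targets).
    """

    seed: int
    n_layers: tuple[int, int] = (1, 3)
    layer_size: tuple[int, int] = (2, 5)
    h: tuple[float, float] = (0.3, 1.2)
    domain_halfwidth: tuple[float, float] = (0.5, 2.0)
    theta: tuple[float, float] = (0.5, 4.0)
    nu: tuple[float, float] = (-1.0, 0.0)
    regime: str = "unconstrained"

    def __post_init__(self) -> None:
        if self.regime not in ("unconstrained", "stable", "unstable"):
            raise ConfigurationError(f"unknown regime {self.regime!r}")


def _draw_model(spec: FixtureSpec, rng: np.random.Generator) -> ModelSpec:
    if spec.regime == "unconstrained":
        L = int(rng.integers(spec.n_layers[0], spec.n_layers[1] + 1))
    else:
        L = 1  # regime targets are defined for the single-layer criterion
    sizes = rng.integers(spec.layer_size[0], spec.layer_size[1] + 1, size=L)
    half = rng.uniform(*spec.domain_halfwidth)
    disc = DiscretizationParams(h=float(rng.uniform(*spec.h)), a=-half, b=half)
    arch_positions = []
    for m in sizes:
        # independent jittered grids keep layers distinguishable
        base = disc.a + (np.arange(m) + 0.5) * disc.omega / m
        jitter = rng.uniform(-0.2, 0.2, size=m) * disc.omega / m
        arch_positions.append(base + jitter)
    arch = LayerArchitecture(sizes=tuple(int(m) for m in sizes),
                             positions=tuple(arch_positions))
    kernel = KernelSpec(
        family="difference",
        base_family="gaussian",
        sigma_plus=float(rng.uniform(0.5, 3.0)),
        sigma_minus=float(rng.uniform(0.1, 1.0)),
        sigma1=float(rng.uniform(0.3, 1.0)),
        sigma2=float(rng.uniform(1.5, 4.0)),
    )
    connectivity = build_connectivity(arch, kernel)
    activation = ActivationSpec(family="sigmoid", theta=float(rng.uniform(*spec.theta)))
    stimulus = StimulusSpec(nu=float(rng.uniform(*spec.nu)), form="zero")
    return ModelSpec(
        architecture=arch,
        discretization=disc,
        connectivity=connectivity,
        activation=activation,
        stimulus=stimulus,
    )


def generate_fixture(spec: FixtureSpec, max_attempts: int = 50) -> ModelSpec:
    """Draw a random model; deterministic in ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    for _ in range(max_attempts):
        model = _draw_model(spec, rng)
        if spec.regime == "unconstrained":
            return model
        if spec.regime == "stable":
            zero = model.uniform_state(0.0)
            mu = mu_single_layer(model, zero)
            max_mu = float(np.max(np.abs(mu)))
            if max_mu == 0.0:
                continue
            target = float(rng.uniform(0.4, 0.85))
            model = _rescale(model, target / max_mu)
            return model
        # unstable: plant a fixed point and push the spectral radius past 1
        model, _ = _plant_fixed_point(model, rng, rho_target=1.2)
        if model is not None:
            return model
    raise ConfigurationError(
        f"could not generate a {spec.regime!r} fixture in {max_attempts} attempts"
    )


def _rescale(model: ModelSpec, factor: float) -> ModelSpec:
    return ModelSpec(
        architecture=model.architecture,
        discretization=model.discretization,
        connectivity=model.connectivity.scaled(factor),
        activation=model.activation,
        stimulus=model.stimulus,
    )


def _with_planted_stimulus(model: ModelSpec, v_star: FieldState) -> ModelSpec:
    """Replace the stimulus so that ``v_star`` is an exact equilibrium.

    The equilibrium condition V = Gamma G(V) + S is solved for S.
    """
    arch = model.architecture
    zero_stim = ModelSpec(
        architecture=arch,
        discretization=model.discretization,
        connectivity=model.connectivity,
        activation=model.activation,
        stimulus=StimulusSpec(nu=0.0, form="zero"),
    )
    coupling = interaction_map(zero_stim, v_star.V)  # Gamma G(V*), S = 0
    values = tuple(
        (v_star.V[k, : arch.sizes[k]] - coupling[k, : arch.sizes[k]]).copy()
        for k in range(arch.n_layers)
    )
    return ModelSpec(
        architecture=arch,
        discretization=model.discretization,
        connectivity=model.connectivity,
        activation=model.activation,
        stimulus=StimulusSpec(nu=0.0, form="explicit", values=values),
    )


def _plant_fixed_point(
    model: ModelSpec,
    rng: np.random.Generator,
    rho_target: float,
) -> tuple[ModelSpec | None, FieldState | None]:
    """Scale weights to hit a spectral-radius target at a planted equilibrium."""
    arch = model.architecture
    v_star = model.uniform_state(0.0)
    V = v_star.V.copy()
    for k, m in enumerate(arch.sizes):
        V[k, :m] = rng.uniform(-1.0, 1.0, size=m)
    v_star = FieldState(V=V)
    alpha = model.discretization.alpha
    base = build_jacobian(_with_planted_stimulus(model, v_star), v_star)
    B = base - alpha * np.eye(base.shape[0])  # the weight-proportional part
    rho_B = float(np.max(np.abs(np.linalg.eigvals(B))))
    if rho_B < 1e-12:
        return None, None
    # rho(alpha I + s B) is monotone-ish in s; bracket and bisect on it
    def rho(s: float) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(alpha * np.eye(B.shape[0]) + s * B))))

    lo, hi = 0.0, 1.0
    while rho(hi) < rho_target:
        hi *= 2.0
        if hi > 1e6:
            return None, None
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if rho(mid) < rho_target:
            lo = mid
        else:
            hi = mid
    scaled = _rescale(model, hi)
    planted = _with_planted_stimulus(scaled, v_star)
    return planted, v_star


def fixture_with_fixed_point(
    seed: int,
    regime: str,
    layer_size: tuple[int, int] = (3, 8),
) -> tuple[ModelSpec, FieldState]:
    """Single-layer sigmoid model with an exact, regime-controlled equilibrium.

    Returns ``(model, v_star)`` where ``v_star`` satisfies the equilibrium
    condition to machine precision and the Jacobian spectral radius at it is
    below 0.9 (``regime='stable'``) or above 1.1 (``regime='unstable'``).
    """
    if regime not in ("stable", "unstable"):
        raise ConfigurationError(f"regime must be 'stable' or 'unstable', got {regime!r}")
    rng = np.random.default_rng(seed)
    target = 1.2 if regime == "unstable" else 0.75
    for _ in range(50):
        model = _draw_model(
            FixtureSpec(seed=seed, regime="unconstrained", n_layers=(1, 1),
                        layer_size=layer_size),
            rng,
        )
        planted, v_star = _plant_fixed_point(model, rng, rho_target=target)
        if planted is None:
            continue
        # verify the planted equilibrium really is one
        resid = np.max(np.abs(interaction_map(planted, v_star.V) - v_star.V))
        A = build_jacobian(planted, v_star)
        rho = float(np.max(np.abs(np.linalg.eigvals(A))))
        ok = rho < 0.9 if regime == "stable" else rho > 1.1
        if resid < 1e-10 and ok:
            return planted, v_star
    raise ConfigurationError(f"failed to build a {regime} fixture for seed {seed}")
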