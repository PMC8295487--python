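"""Spatial and temporal discretization of a neural-field domain.

The field lives on a bounded interval Omega = [a, b] carrying L layers of
neurons.  Each layer k holds M_k neurons placed on a midpoint grid, and the
per-layer Riemann weight beta_k = |Omega| / M_k turns the lateral-interaction
integral into a sum.  Time is discretized with a constant step h through the
exact relaxation factor alpha = exp(-h): after one step with no input a
potential decays by exactly alpha, matching the continuous leak term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError

__all__ = [
    "DiscretizationParams",
    "LayerArchitecture",
    "make_grid",
]


@dataclass(frozen=True)
class DiscretizationParams:
    """Time step and spatial domain of the lattice model.

    Parameters
    ----------
    h
        Time step (dimensionless, in units of the membrane time constant).
        Must be positive.
    a, b
        Domain bounds, ``a < b``; ``|Omega| = b - a``.
    alpha_override
        Optional explicit memory factor in ``(0, 1]`` replacing
        ``exp(-h)``.  ``alpha_override = 1`` freezes the field (every update
        returns the state unchanged), which is the degenerate end point of
        the relaxation-rate sweep.
    """

    h: float
    a: float
    b: float
    alpha_override: float | None = None

    def __post_init__(self) -> None:
        if not (self.h > 0 and math.isfinite(self.h)):
            raise ConfigurationError(f"time step h must be positive, got {self.h}")
        if not (self.a < self.b):
            raise ConfigurationError(f"domain requires a < b, got [{self.a}, {self.b}]")
        if self.alpha_override is not None and not (0.0 < self.alpha_override <= 1.0):
            raise ConfigurationError(
                f"alpha override must lie in (0, 1], got {self.alpha_override}"
            )

    @property
    def alpha(self) -> float:
        """Per-step memory factor alpha = exp(-h) (or the explicit override)."""
        if self.alpha_override is not None:
            return self.alpha_override
        return math.exp(-self.h)

    @property
    def phi(self) -> float:
        """Time-scale factor phi(h) = 1 - exp(-h); alpha + phi = 1."""
        return 1.0 - self.alpha

    @property
    def omega(self) -> float:
        """Domain length |Omega| = b - a."""
        return self.b - self.a

    def beta(self, m: int) -> float:
        """Riemann weight |Omega| / m of a layer with m neurons."""
        if m < 1:
            raise ConfigurationError(f"layer size must be >= 1, got {m}")
        return self.omega / m


def make_grid(params: DiscretizationParams, m: int) -> np.ndarray:
    """Midpoint-rule grid of ``m`` coordinates on [a, b].

    x_i = a + (i - 1/2) |Omega| / m for i = 1..m, so each node sits at the
    center of its Riemann cell and the cell width equals beta = |Omega|/m.
    """
    if m < 1:
        raise ConfigurationError(f"grid size must be >= 1, got {m}")
    step = params.omega / m
    return params.a + (np.arange(m) + 0.5) * step


@dataclass(frozen=True)
class LayerArchitecture:
    """Layer sizes, neuron positions, and the chain of layer adjacencies.

    Layers form a line graph: layer k talks to itself and to layers k-1 and
    k+1 (when they exist).  ``positions[k]`` holds the coordinates of the
    ``sizes[k]`` neurons of layer k (0-based layer indices throughout the
    code; serialization uses 1-based labels).
    """

    sizes: tuple[int, ...]
    positions: tuple[np.ndarray, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.sizes) == 0:
            raise ConfigurationError("at least one layer is required")
        if any(m < 1 for m in self.sizes):
            raise ConfigurationError(f"empty layer in sizes {self.sizes}")
        if len(self.positions) != len(self.sizes):
            raise ConfigurationError("positions must be given for every layer")
        for k, (m, pos) in enumerate(zip(self.sizes, self.positions)):
            if len(pos) != m:
                raise ConfigurationError(
                    f"layer {k}: {m} neurons but {len(pos)} positions"
                )

    @property
    def n_layers(self) -> int:
        return len(self.sizes)

    @property
    def max_size(self) -> int:
        """M = max_k M_k, the padded row length of the field matrix."""
        return max(self.sizes)

    @property
    def total_size(self) -> int:
        """Sum of all layer sizes (dimension of the super-adjacency matrix)."""
        return sum(self.sizes)

    def neighbors(self, k: int) -> tuple[int, ...]:
        """Layer-neighbor set L_k of layer k (0-based), including k itself."""
        L = self.n_layers
        if not 0 <= k < L:
            raise ConfigurationError(f"layer index {k} out of range for L={L}")
        if L == 1:
            return (0,)
        if k == 0:
            return (0, 1)
        if k == L - 1:
            return (L - 2, L - 1)
        return (k - 1, k, k + 1)

    @classmethod
    def uniform(
        cls, params: DiscretizationParams, n_layers: int, m: int
    ) -> "LayerArchitecture":
        """All layers share the same midpoint grid of ``m`` neurons."""
        grid = make_grid(params, m)
        return cls(sizes=(m,) * n_layers, positions=(grid,) * n_layers)

    @classmethod
    def layered_line(
        cls, params: DiscretizationParams, n_layers: int
    ) -> "LayerArchitecture":
        """One neuron per layer; layer k sits at the k-th midpoint of Omega.

        This realizes the stacked-single-neuron architecture whose adjacency
        matrix is tridiagonal: the chain of layers doubles as a chain of
        positions, so intra- and inter-layer weights can be drawn from the
        same spatial kernel.
        """
        grid = make_grid(params, n_layers)
        return cls(
            sizes=(1,) * n_layers,
            positions=tuple(np.array([x]) for x in grid),
        )
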