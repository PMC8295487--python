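"""Connection-intensity kernels and the block-structured connectivity tensor.

The lateral interaction between two neurons at coordinates x and y is set by
a kernel W(x, y).  Four families are supported:

* ``gaussian``   Gau(x, y, sigma) = (sigma sqrt(2 pi))^-1 exp(-|x-y|^2 / (2 sigma^2))
* ``laplacian``  Lap(x, y, sigma) = (2 sigma)^-1 exp(-|x-y| / sigma)
* ``tanh``       Thyp(x, y, beta, r) = 1 + tanh(beta x.y + r)  (inner product,
  asymmetric by construction; no symmetrization is applied)
* ``difference`` sigma_plus * base(x, y, p1) - sigma_minus * base(x, y, p2),
  the lateral-inhibition ("Mexican hat") profile: short-range excitation with
  amplitude sigma_plus and width p1, minus long-range inhibition with
  amplitude sigma_minus and width p2 > p1.

Weights between layers k and l are nonzero only when the layers are adjacent
in the line graph of layers; those blocks are identically zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .exceptions import ConfigurationError, InputError

if TYPE_CHECKING:  # pragma: no cover
    from .model import LayerArchitecture

__all__ = [
    "KernelSpec",
    "ConnectivityTensor",
    "evaluate_kernel",
    "build_connectivity",
    "kernel_bound",
    "KERNEL_PRESETS",
]

_FAMILIES = ("gaussian", "laplacian", "tanh", "difference")


@dataclass(frozen=True)
class KernelSpec:
    """Parameters of one connection-intensity function.

    For ``gaussian``/``laplacian``: ``sigma`` is the width.
    For ``tanh``: ``beta`` (slope) and ``r`` (offset).
    For ``difference``: ``base_family`` selects the component family;
    ``sigma_plus``/``sigma_minus`` are the excitatory/inhibitory amplitudes;
    ``sigma1``/``sigma2`` the component widths (``beta1``/``beta2`` plus a
    shared ``r`` when the base is ``tanh``).
    """

    family: str
    sigma: float | None = None
    beta: float | None = None
    r: float | None = None
    sigma_plus: float | None = None
    sigma_minus: float | None = None
    sigma1: float | None = None
    sigma2: float | None = None
    beta1: float | None = None
    beta2: float | None = None
    base_family: str = "gaussian"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigurationError(
                f"unknown kernel family {self.family!r}; expected one of {_FAMILIES}"
            )
        if self.family in ("gaussian", "laplacian"):
            if self.sigma is None or not self.sigma > 0:
                raise ConfigurationError(
                    f"{self.family} kernel requires sigma > 0, got {self.sigma}"
                )
        elif self.family == "tanh":
            if self.beta is None or self.r is None:
                raise ConfigurationError("tanh kernel requires beta and r")
        else:  # difference
            if self.base_family not in ("gaussian", "laplacian", "tanh"):
                raise ConfigurationError(
                    f"unknown difference base family {self.base_family!r}"
                )
            if self.sigma_plus is None or self.sigma_minus is None:
                raise ConfigurationError(
                    "difference kernel requires sigma_plus and sigma_minus"
                )
            if self.sigma_plus < 0 or self.sigma_minus < 0:
                raise ConfigurationError("difference amplitudes must be nonnegative")
            if self.base_family in ("gaussian", "laplacian"):
                if not (self.sigma1 and self.sigma1 > 0 and self.sigma2 and self.sigma2 > 0):
                    raise ConfigurationError(
                        "difference kernel requires component widths sigma1, sigma2 > 0"
                    )
            else:
                if self.beta1 is None or self.beta2 is None or self.r is None:
                    raise ConfigurationError(
                        "tanh-difference kernel requires beta1, beta2 and r"
                    )

    def component(self, which: int) -> "KernelSpec":
        """Base-family spec of the excitatory (1) or inhibitory (2) lobe."""
        if self.family != "difference":
            raise ConfigurationError("component() only applies to difference kernels")
        if self.base_family == "tanh":
            beta = self.beta1 if which == 1 else self.beta2
            return KernelSpec(family="tanh", beta=beta, r=self.r)
        sigma = self.sigma1 if which == 1 else self.sigma2
        return KernelSpec(family=self.base_family, sigma=sigma)


def evaluate_kernel(spec: KernelSpec, x, y):
    """Evaluate W(x, y); accepts scalars or broadcastable arrays."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InputError("kernel coordinates must be finite")
    if spec.family == "gaussian":
        s = spec.sigma
        val = np.exp(-0.5 * np.abs(x - y) ** 2 / s**2) / (s * math.sqrt(2.0 * math.pi))
    elif spec.family == "laplacian":
        s = spec.sigma
        val = np.exp(-np.abs(x - y) / s) / (2.0 * s)
    elif spec.family == "tanh":
        val = 1.0 + np.tanh(spec.beta * x * y + spec.r)
    else:  # difference of two base kernels
        val = np.asarray(
            spec.sigma_plus * evaluate_kernel(spec.component(1), x, y)
            - spec.sigma_minus * evaluate_kernel(spec.component(2), x, y)
        )
    return val if val.ndim else float(val)


@dataclass(frozen=True)
class ConnectivityTensor:
    """Block-structured synaptic weights W_ij^(k,l) over a layered architecture.

    ``blocks[(k, l)]`` is the M_k x M_l weight matrix from layer l onto layer
    k (0-based).  Blocks between non-adjacent layers are identically zero and
    stored as zero matrices.
    """

    layer_sizes: tuple[int, ...]
    blocks: dict[tuple[int, int], np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        L = len(self.layer_sizes)
        for (k, l), block in self.blocks.items():
            if not (0 <= k < L and 0 <= l < L):
                raise ConfigurationError(f"block index {(k, l)} out of range")
            expected = (self.layer_sizes[k], self.layer_sizes[l])
            if block.shape != expected:
                raise ConfigurationError(
                    f"block {(k, l)} has shape {block.shape}, expected {expected}"
                )
            if not np.all(np.isfinite(block)):
                raise ConfigurationError(f"block {(k, l)} contains non-finite weights")

    def block(self, k: int, l: int) -> np.ndarray:
        """Weight matrix from layer l onto layer k (zeros if absent)."""
        got = self.blocks.get((k, l))
        if got is None:
            return np.zeros((self.layer_sizes[k], self.layer_sizes[l]))
        return got

    @property
    def w0(self) -> float:
        """Uniform weight bound W0 = max |W_ij^(k,l)| over all blocks."""
        return kernel_bound(self)

    def scaled(self, factor: float) -> "ConnectivityTensor":
        return ConnectivityTensor(
            layer_sizes=self.layer_sizes,
            blocks={kl: factor * b for kl, b in self.blocks.items()},
        )


def build_connectivity(arch: "LayerArchitecture", spec: KernelSpec) -> ConnectivityTensor:
    """Assemble W_ij^(k,l) = W(x_i^(k), y_j^(l)) on the adjacent-layer blocks.

    Blocks between non-adjacent layers are left as exact zeros, encoding the
    line-graph coupling structure of the layered field.
    """
    blocks: dict[tuple[int, int], np.ndarray] = {}
    for k in range(arch.n_layers):
        xk = arch.positions[k]
        for l in range(arch.n_layers):
            if l in arch.neighbors(k):
                yl = arch.positions[l]
                blocks[(k, l)] = np.asarray(
                    evaluate_kernel(spec, xk[:, None], yl[None, :]), dtype=float
                )
            else:
                blocks[(k, l)] = np.zeros((arch.sizes[k], arch.sizes[l]))
    return ConnectivityTensor(layer_sizes=tuple(arch.sizes), blocks=blocks)


def kernel_bound(tensor: ConnectivityTensor) -> float:
    """W0 = max absolute synaptic weight; enters the contraction product C W0."""
    best = 0.0
    for block in tensor.blocks.values():
        if block.size:
            best = max(best, float(np.max(np.abs(block))))
    return best


#: Named kernel parameter sets used by the shipped scenarios.  The
#: ``gauss_diff_sec35`` difference-of-Gaussians (excitation 4.0/width 1,
#: inhibition 1.5/width 4.5) drives all simulation scenarios; the ``fig3_*``
#: sets reproduce the illustrative kernel plots (excitation amplitude 4.5).
KERNEL_PRESETS: dict[str, KernelSpec] = {
    "gauss_diff_sec35": KernelSpec(
        family="difference",
        base_family="gaussian",
        sigma_plus=4.0,
        sigma_minus=1.5,
        sigma1=1.0,
        sigma2=4.5,
    ),
    "fig3_gauss_diff": KernelSpec(
        family="difference",
        base_family="gaussian",
        sigma_plus=4.5,
        sigma_minus=1.5,
        sigma1=1.0,
        sigma2=4.5,
    ),
    "fig3_lap_diff": KernelSpec(
        family="difference",
        base_family="laplacian",
        sigma_plus=4.5,
        sigma_minus=1.5,
        sigma1=1.0,
        sigma2=4.5,
    ),
    "fig3_tanh_diff": KernelSpec(
        family="difference",
        base_family="tanh",
        sigma_plus=4.5,
        sigma_minus=1.5,
        beta1=0.1,
        beta2=0.5,
        r=-0.1,
    ),
}
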