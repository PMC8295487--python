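"""Pulse-emission rate functions G mapping membrane potential to activity.

Two gains are shipped: the logistic sigmoid
``G(v) = (1 + exp(-theta (v - v0)))^-1`` with steepness ``theta`` and
threshold ``v0``, and the hard threshold (Heaviside) ``G(v) = 1`` for
``v > v0``, else 0 — the open-interval indicator, so the threshold itself
emits nothing.

The derivative of the step function exists only distributionally (a Dirac
mass at ``v0``); off the threshold it is zero, and querying it within
``SINGULARITY_TOL`` of the threshold raises ``ThresholdSingularityError``
so that linearizations never silently land on the singular point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (
    ConfigurationError,
    InputError,
    NotLipschitzError,
    ThresholdSingularityError,
)

__all__ = [
    "ActivationSpec",
    "evaluate_activation",
    "activation_derivative",
    "lipschitz_constant",
    "SINGULARITY_TOL",
]

#: Absolute guard band around the Heaviside threshold within which the
#: distributional derivative (Dirac mass) is considered hit.
SINGULARITY_TOL = 1e-9


@dataclass(frozen=True)
class ActivationSpec:
    """Gain family with steepness ``theta`` (sigmoid only) and threshold ``v0``."""

    family: str
    theta: float = 1.0
    v0: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("sigmoid", "heaviside"):
            raise ConfigurationError(
                f"unknown activation family {self.family!r}; "
                "expected 'sigmoid' or 'heaviside'"
            )
        if self.family == "sigmoid" and not self.theta > 0:
            raise ConfigurationError(f"sigmoid requires theta > 0, got {self.theta}")


def evaluate_activation(spec: ActivationSpec, v):
    """G(v); scalar or elementwise on arrays."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise InputError("activation input must be finite")
    if spec.family == "sigmoid":
        out = 1.0 / (1.0 + np.exp(-spec.theta * (v - spec.v0)))
    else:
        out = (v > spec.v0).astype(float)
    return out if out.ndim else float(out)


def activation_derivative(spec: ActivationSpec, v):
    """G'(v): theta G (1 - G) for the sigmoid; 0 off-threshold for the step.

    Raises
    ------
    ThresholdSingularityError
        For a Heaviside gain evaluated within ``SINGULARITY_TOL`` of the
        threshold, where the derivative is a Dirac mass.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise InputError("activation input must be finite")
    if spec.family == "sigmoid":
        g = 1.0 / (1.0 + np.exp(-spec.theta * (v - spec.v0)))
        out = spec.theta * g * (1.0 - g)
        return out if out.ndim else float(out)
    if np.any(np.abs(v - spec.v0) <= SINGULARITY_TOL):
        raise ThresholdSingularityError(
            "Heaviside derivative requested on the threshold (Dirac mass at "
            f"v0={spec.v0}); distributional derivative is not a number there"
        )
    out = np.zeros_like(v)
    return out if out.ndim else float(out)


def lipschitz_constant(spec: ActivationSpec) -> float:
    """Global Lipschitz constant of G: theta/4 for the sigmoid.

    The sigmoid derivative theta G (1 - G) is maximized at G = 1/2.  The
    step function has no finite Lipschitz constant.
    """
    if spec.family != "sigmoid":
        raise NotLipschitzError(
            "the Heaviside gain is discontinuous and has no Lipschitz constant"
        )
    return spec.theta / 4.0
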