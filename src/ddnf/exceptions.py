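"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A model, kernel, or scenario specification is invalid."""


class InputError(ValueError):
    """Runtime inputs (states, coordinates, indices) are malformed."""


class ThresholdSingularityError(ArithmeticError):
    """A Heaviside derivative was requested on (or too close to) the threshold.

    The distributional derivative of the step function is a Dirac mass at the
    threshold; linearization is undefined there.
    """


class NotLipschitzError(ValueError):
    """A Lipschitz constant was requested for a discontinuous gain function."""


class NonConvergenceError(RuntimeError):
    """An iterative solve exhausted its iteration budget."""
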