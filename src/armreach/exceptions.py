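"""Exception types shared across the package."""


class ArmReachError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(ArmReachError, ValueError):
    """An argument violates a documented precondition."""


class UnreachableTargetError(ArmReachError, ValueError):
    """A fingertip position lies outside the reachable annulus.

    Attributes
    ----------
    distance : float
        Requested shoulder-to-fingertip distance (m).
    lower, upper : float
        Reachable bounds |L1 - r| and L1 + r for the current wrist angle.
    time : float or None
        First offending sample time when raised while sampling a trajectory.
    """

    def __init__(self, distance, lower, upper, time=None):
        self.distance = float(distance)
        self.lower = float(lower)
        self.upper = float(upper)
        self.time = time
        where = "" if time is None else f" at t={time:.4f} s"
        super().__init__(
            f"fingertip distance {distance:.4f} m outside reachable annulus "
            f"[{lower:.4f}, {upper:.4f}] m{where}"
        )


class ConvergenceError(ArmReachError, RuntimeError):
    """An iterative scheme failed to converge within its iteration budget."""

    def __init__(self, message, residual=None):
        self.residual = residual
        super().__init__(message)


class TensionSolverError(ArmReachError, RuntimeError):
    """The muscle-tension quadratic program could not be solved."""


class IntegrationDivergenceError(ArmReachError, RuntimeError):
    """Forward dynamics produced a non-finite state."""


class OnsetDetectionError(ArmReachError, RuntimeError):
    """Movement onset/offset detection found no curvature crossing."""

    def __init__(self, side):
        self.side = side
        super().__init__(f"no curvature-threshold crossing found on the {side} side")
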