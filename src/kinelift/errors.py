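"""Exception types used across the package."""


class InvalidInputError(ValueError):
    """An argument violates a documented precondition (shape, range, finiteness)."""


class DegenerateGeometryError(InvalidInputError):
    """Geometry for which the requested quantity is undefined.

    Raised e.g. for the bone-length gradient when two connected joints
    coincide: the residual is still defined but its derivative is not.
    """


class SolverDiagnosticError(RuntimeError):
    """Numerical failure inside the alternating solver.

    Carries the last finite solver state (when available) so that a caller
    can inspect penalty weights and residuals at the point of failure.
    """

    def __init__(self, message, state=None):
        super().__init__(message)
        self.state = state
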