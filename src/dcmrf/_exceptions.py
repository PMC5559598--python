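"""Exception hierarchy for dcmrf."""


class DCMRFError(Exception):
    """Base class for all dcmrf errors."""


class InputDomainError(DCMRFError, ValueError):
    """An input is outside the physical or numerical domain of an operation."""


class SingularModelError(DCMRFError, ValueError):
    """The two agents' relaxivities are (numerically) linearly dependent.

    The dual-agent inversion divides by the relaxivity determinant
    ``r2A*r1B - r1A*r2B``; when the two agents have near-proportional
    (r1, r2) pairs the system is degenerate and concentrations cannot be
    separated.
    """


class DegenerateDesignError(DCMRFError, ValueError):
    """A regression design carries no information (e.g. one unique abscissa)."""


class FitFailureError(DCMRFError, RuntimeError):
    """A nonlinear fit failed to converge.

    Attributes
    ----------
    diagnostics : dict
        Solver messages, initial values tried, and the offending data summary.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
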