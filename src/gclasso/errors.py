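"""Exception hierarchy.

CLI exit codes: InputError -> 2, ConvergenceError -> 3.
"""


class GclassoError(Exception):
    """Base class for all package errors."""


class InputError(GclassoError):
    """Invalid user input: malformed files, bad labels, invalid parameters."""


class ConvergenceError(GclassoError):
    """An iterative solver failed to reach its tolerance."""


class DegenerateDesignError(GclassoError):
    """A design (sub)matrix is rank deficient or numerically collinear."""
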