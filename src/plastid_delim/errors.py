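"""Exception hierarchy for the pipeline.

Input problems (bad files, inconsistent labels) raise :class:`InputError`
subclasses; numerical failures (non-convergent optimisation) raise
:class:`NumericalError`.  The CLI maps these to exit codes 2 and 3.
"""


class PlastidDelimError(Exception):
    """Base class for all package errors."""


class InputError(PlastidDelimError):
    """Malformed or inconsistent input data."""


class AlignmentError(InputError):
    """Alignment violates an invariant (ragged rows, bad characters...)."""


class TreeError(InputError):
    """Tree violates an invariant (non-ultrametric, polytomy, unrooted...)."""


class SpeciesMapError(InputError):
    """Tip-to-species assignment table problem."""


class NumericalError(PlastidDelimError):
    """Optimisation or numerical routine failed to converge."""
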