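"""Exception hierarchy shared across the pipeline.

Two broad classes matter for the command line: problems with what the user
supplied (:class:`InputError`, exit status 2) and problems arising while
computing (:class:`ComputationError`, exit status 3).
"""


class AlpsimError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(AlpsimError):
    """Invalid user-supplied data, file, or parameter."""

    exit_code = 2


class ParameterError(InputError):
    """A scalar parameter is out of its valid range."""


class GeometryError(InputError):
    """Phantom or ROI geometry is inconsistent (overlaps, out of bounds)."""


class FormatError(InputError):
    """A file on disk could not be parsed or is internally inconsistent."""


class ComputationError(AlpsimError):
    """A numerically valid input produced an unusable result."""

    exit_code = 3


class SelectionError(ComputationError):
    """No valid voxel could be selected for an ALPS measurement."""
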