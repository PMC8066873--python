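"""Exception hierarchy.

The command line maps these onto distinct exit codes so that callers can
tell bad arguments (2) from bad data (3) from numerical failures (4).
"""


class NvcPipeError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ParameterError(NvcPipeError):
    """Invalid argument or configuration value."""

    exit_code = 2


class DataError(NvcPipeError):
    """Input data violates a contract (shape, sign, missing wavelength...)."""

    exit_code = 3


class NumericalError(NvcPipeError):
    """A numerical procedure failed (singular system, rank deficiency...)."""

    exit_code = 4
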