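"""Exception hierarchy.

Input/validation problems and numerical failures are kept distinct so the
command-line layer can map them onto different exit codes (2 and 3).
"""


class PymbmsError(Exception):
    """Base class for all package errors."""


class InputError(PymbmsError, ValueError):
    """Invalid input data or configuration (CLI exit code 2)."""


class NumericalError(PymbmsError, RuntimeError):
    """Numerical failure such as non-convergence (CLI exit code 3)."""
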