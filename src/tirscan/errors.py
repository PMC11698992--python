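"""Exception hierarchy with CLI exit codes.

Every error raised by the library derives from :class:`TirError`.  The CLI
maps subclasses to distinct exit codes so that callers can distinguish a
missing input (3) from a malformed one (4) from a stage-level failure (5).
"""


class TirError(Exception):
    """Base class for all tirscan errors."""

    exit_code = 1


class InputError(TirError):
    """An input file is missing, empty or unreadable."""

    exit_code = 3


class ValidationError(TirError):
    """Inputs parse but violate a documented invariant or schema."""

    exit_code = 4


class StageError(TirError):
    """A pipeline stage failed while processing valid inputs."""

    exit_code = 5


class InfeasibleConfigError(ValidationError):
    """A simulation config cannot be realized (e.g. window too small)."""


class AnchorNotFoundError(StageError):
    """The 5'-start anchor is absent from a junction read.

    Distinct from an ``other`` end-variant call: without the anchor the
    junction itself cannot be located.
    """
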