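"""Exception hierarchy shared across the pipeline.

``InputError`` marks problems with user-supplied files or parameters
(CLI exit code 2); ``InvariantError`` marks violations of internal
contracts that indicate corrupt or inconsistent data (exit code 3).
"""


class CdpkFamError(Exception):
    """Base class for all package-specific errors."""


class InputError(CdpkFamError):
    """A user-supplied file or parameter is missing or malformed."""


class InvariantError(CdpkFamError):
    """An internal data-structure invariant was violated."""
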