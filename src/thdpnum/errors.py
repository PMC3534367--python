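"""Exception hierarchy.

``InputError`` marks problems with user-supplied data (bad files, malformed
sequences, contract violations); the CLI maps it to exit code 2.  Everything
else is an internal error (exit code 1).
"""


class ThdpnumError(Exception):
    """Base class for all package errors."""


class InputError(ThdpnumError):
    """Invalid user input: missing/malformed file, bad sequence, bad ids."""


class GateRejection(ThdpnumError):
    """A query sequence failed the profile-score acceptance gate."""

    def __init__(self, message, gate_result=None):
        super().__init__(message)
        self.gate_result = gate_result
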