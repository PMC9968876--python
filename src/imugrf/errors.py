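"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: usage problems -> 2, data/contract
violations -> 3.
"""


class ImuGrfError(Exception):
    """Base class for all package errors."""


class FormatError(ImuGrfError):
    """A file does not match the expected on-disk dialect."""


class DataError(ImuGrfError):
    """File parsed but its contents violate a data invariant."""


class ContractError(ImuGrfError):
    """A caller violated an operation precondition."""


class SyncError(ImuGrfError):
    """Foot-stomp synchronization could not be established."""


class DetectionError(ImuGrfError):
    """Gait-event detection failed on a signal that should contain events."""


class AlignmentError(ImuGrfError):
    """Clock-drift correction could not pair initial-contact events."""


class TrainingError(ImuGrfError):
    """Model training diverged (e.g. NaN loss)."""
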