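"""Exception hierarchy with distinct CLI exit codes."""


class StackQuantError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(StackQuantError):
    """Invalid or inconsistent configuration (bad parameter, missing channel)."""

    exit_code = 3


class InputError(StackQuantError):
    """Unreadable or malformed input data (TIFF, CSV, sidecar)."""

    exit_code = 4


class ComputationError(StackQuantError):
    """A computation could not be carried out on otherwise valid inputs."""

    exit_code = 5


class PlacementError(ComputationError):
    """Synthetic scene could not place all cells within the attempt budget."""
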