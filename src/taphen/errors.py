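"""Exception hierarchy shared by all taphen modules."""


class TaphenError(Exception):
    """Base class for all taphen errors."""


class FormatError(TaphenError, ValueError):
    """A file exists but its content violates the expected format."""


class ContractError(TaphenError, ValueError):
    """An operation was called with arguments violating its contract."""


class PlacementError(TaphenError, RuntimeError):
    """The synthetic-scene generator could not place the requested objects.

    Carries ``achieved``, the number of cells successfully placed before
    giving up.
    """

    def __init__(self, message: str, achieved: int):
        super().__init__(message)
        self.achieved = achieved
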