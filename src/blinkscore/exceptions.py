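"""Exception hierarchy shared across the package."""


class BlinkscoreError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(BlinkscoreError, ValueError):
    """Degenerate landmark geometry (e.g. coincident eye corners)."""


class EmptyDataError(BlinkscoreError, ValueError):
    """No usable data: empty recording, all-missing series, empty group."""


class InvalidParameterError(BlinkscoreError, ValueError):
    """An input value violates a documented precondition."""


class DegenerateStatisticError(BlinkscoreError, ValueError):
    """A test statistic is undefined for the given inputs."""


class PlacementError(BlinkscoreError, ValueError):
    """Requested synthetic events cannot be placed without overlap."""
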