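"""Exception types shared across the toolkit."""


class MicrorheoError(Exception):
    """Base class for all toolkit errors."""


class FormatError(MicrorheoError):
    """Unknown or unreadable trajectory/stress format."""


class BoxError(MicrorheoError):
    """Missing or unusable simulation box."""


class TimingError(MicrorheoError):
    """Non-uniform or non-monotone frame times."""


class SelectionError(MicrorheoError):
    """Requested particles/probes are absent."""


class DimensionError(MicrorheoError):
    """Axis mask leaves fewer than two tracked dimensions."""


class GridError(MicrorheoError):
    """Mismatched or out-of-range lag/τ/ω grids."""


class WindowError(MicrorheoError):
    """Invalid fitting window."""


class FitError(MicrorheoError):
    """Optimizer failed to converge."""


class NumericError(MicrorheoError):
    """Numerical failure (NaN/zero transform, special-function breakdown)."""


class TerminalRegionError(MicrorheoError):
    """Requested window is not in the terminal (G″ ∝ ω) regime."""


class InputError(MicrorheoError):
    """Missing/invalid input data (e.g. stress components)."""


class AmbiguityError(MicrorheoError):
    """Unwrap is ill-posed (per-frame displacement beyond half a box edge)."""
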