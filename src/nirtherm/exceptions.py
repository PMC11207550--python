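"""Exception hierarchy for the pipeline.

Configuration problems (bad parameter values, overlapping event ranges) raise
:class:`ConfigError`; malformed data containers (wrong cycle length, wrong frame
count) raise :class:`DataFormatError`; physically invalid signals (non-positive
intensity entering the log) raise :class:`SignalError`; out-of-domain queries
(temperature outside the trace span) raise :class:`RangeError`.
"""


class NIRThermError(Exception):
    """Base class for all package errors."""


class ConfigError(NIRThermError, ValueError):
    """Invalid configuration value."""


class DataFormatError(NIRThermError, ValueError):
    """Malformed input container (wrong shape, length, or schema)."""


class SignalError(NIRThermError, ValueError):
    """Physically invalid signal, e.g. non-positive intensity at a laser."""


class RangeError(NIRThermError, ValueError):
    """Query outside the valid domain (no extrapolation performed)."""


class RankError(NIRThermError, ValueError):
    """Linear-algebra rank deficiency (e.g. response orthogonal to spectra)."""
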