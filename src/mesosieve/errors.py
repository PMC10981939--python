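"""Exception hierarchy.

All package errors derive from :class:`MesosieveError` so callers can catch
one base class; each subclass also derives from ``ValueError`` because every
failure mode here is ultimately a bad value or bad configuration.
"""


class MesosieveError(Exception):
    """Base class for all mesosieve errors."""


class InvalidConfigError(MesosieveError, ValueError):
    """A configuration object violates its invariants."""


class InvalidInputError(MesosieveError, ValueError):
    """A function argument is outside its documented domain."""


class InvalidTruthError(MesosieveError, ValueError):
    """A ground-truth table violates its class invariants."""


class FormatError(MesosieveError, ValueError):
    """An on-disk table violates the package's TSV dialect."""


class DegenerateDataError(MesosieveError, ValueError):
    """Data are degenerate for the requested operation (e.g. zero quantile)."""


class InsufficientDataError(MesosieveError, ValueError):
    """Too few finite observations to perform a fit."""


class UndefinedMetricError(MesosieveError, ValueError):
    """A metric is undefined on this input (e.g. AUC without positives)."""
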