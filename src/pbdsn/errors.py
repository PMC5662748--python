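"""Exception hierarchy.

``InputError`` signals a problem with the data itself (malformed file,
invalid labels, degenerate groups); ``ParameterError`` signals an invalid
argument to an analysis routine. Both derive from :class:`PbdsnError` so
callers can catch everything the package raises with one clause.
"""


class PbdsnError(Exception):
    """Base class for all errors raised by pbdsn."""


class InputError(PbdsnError):
    """The input data violates a requirement (bad file, bad labels, ...)."""


class ParameterError(PbdsnError):
    """An analysis parameter is outside its valid domain."""


class ZeroVarianceError(PbdsnError):
    """A value sequence has zero variance, so a Pearson correlation is
    undefined. Network construction treats this as "no edge"."""
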