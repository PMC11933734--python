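"""Exception hierarchy shared by all esiptkit modules."""


class EsiptkitError(Exception):
    """Base class for all esiptkit errors."""


class ParseError(EsiptkitError):
    """A file could not be parsed under the requested dialect."""


class TopologyError(EsiptkitError):
    """Frames of one ensemble do not share a common atom ordering."""


class ValidationError(EsiptkitError):
    """An input violates a documented contract (duplicate ids, bad sums, ...)."""


class SelectionError(EsiptkitError):
    """An atom or descriptor selector does not resolve in the topology."""


class DegenerateGeometryError(EsiptkitError):
    """Geometry is singular for the requested operation (collinear torsion, zero resultant, ...)."""


class ParameterError(EsiptkitError):
    """An algorithm parameter is out of range for the given data (e.g. k > n_frames)."""


class DomainError(EsiptkitError):
    """A numeric argument is outside the mathematical domain of the operation."""
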