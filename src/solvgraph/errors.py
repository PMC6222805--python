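"""Exception hierarchy for solvgraph.

All errors raised by the package derive from :class:`SolvgraphError`, so
callers (and the CLI) can catch one base class.
"""


class SolvgraphError(Exception):
    """Base class for all solvgraph errors."""


class ParseError(SolvgraphError):
    """A file could not be parsed; the message names the offending line."""


class TopologyError(SolvgraphError):
    """A topology definition is internally inconsistent or does not match a frame."""


class GeometryError(SolvgraphError):
    """Unsupported geometry, e.g. a non-cubic periodic box."""


class AnalysisError(SolvgraphError):
    """An analysis was requested on input for which it is undefined."""
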