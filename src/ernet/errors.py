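"""Exception hierarchy shared across the pipeline stages."""


class ErnetError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ErnetError):
    """A delimited input file could not be parsed; carries the line number."""


class ValidationError(ErnetError):
    """An input violated a structural invariant (counts, uniqueness, ranges)."""


class AlignmentError(ErnetError):
    """Two objects that must share a node/participant ordering do not."""


class DegenerateInputError(ErnetError):
    """Input is structurally valid but the requested quantity is undefined on it."""


class UndefinedMetricError(ErnetError):
    """A graph metric is undefined for this graph (e.g. path length of an edgeless graph)."""


class UndefinedIndexError(ErnetError):
    """Small-world indices cannot be formed (zero null clustering or no finite null path)."""
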