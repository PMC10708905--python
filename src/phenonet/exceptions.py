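"""Exception hierarchy shared across the package."""


class PhenonetError(Exception):
    """Base class for all package-specific errors."""


class InputError(PhenonetError):
    """Malformed input data (unparseable dates, no records, bad values)."""


class SchemaError(InputError):
    """A required column is missing from an input table."""


class ConfigurationError(PhenonetError):
    """Invalid window or run configuration (e.g. overlapping ranges)."""


class EmptyBlockError(PhenonetError):
    """An operation that requires interaction records received none."""


class DimensionError(PhenonetError):
    """Matrix dimensions or labels do not match between two objects."""


class ModelInfeasibleError(PhenonetError):
    """The interaction-probability polynomial has no root in [0, 1].

    Raised when the empirical link count exceeds the number of actor pairs
    with at least one copresence: links require copresence, so such a
    network cannot be produced by the model.
    """


class UndefinedStatisticError(PhenonetError):
    """A confusion-matrix statistic is undefined (zero marginal)."""


class DegenerateNetworkError(PhenonetError):
    """A network violates the minimum-degree convention (e.g. all zeros)."""
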