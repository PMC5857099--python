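"""Exception hierarchy for rbpflow."""


class RbpflowError(Exception):
    """Base class for all rbpflow errors."""


class InvalidConfigError(RbpflowError, ValueError):
    """A simulation or analysis configuration is inconsistent."""


class InvalidInputError(RbpflowError, ValueError):
    """An input table, matrix, or interval violates a precondition."""


class VennInfeasibleError(InvalidConfigError):
    """Requested set sizes cannot be realized; names the violated region."""

    def __init__(self, region: str, count: int):
        self.region = region
        self.count = count
        super().__init__(
            f"infeasible Venn configuration: region {region!r} would need "
            f"{count} elements"
        )


class EmptyGroupError(RbpflowError, ValueError):
    """A composite high/low grouping produced an empty sample group."""


class UndefinedCorrelationError(RbpflowError, ValueError):
    """Correlation requested on a zero-variance vector."""
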