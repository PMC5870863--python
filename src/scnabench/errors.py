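"""Exception hierarchy. CLI maps ConfigError -> exit 2, DataError -> exit 3."""


class ScnabenchError(Exception):
    """Base class for package errors."""


class ConfigError(ScnabenchError):
    """Invalid configuration (bad counts, malformed YAML, impossible design)."""


class DataError(ScnabenchError):
    """Invalid or inconsistent input data (files, coordinates, formats)."""


class PlacementError(DataError):
    """Variant placement failed after the retry cap; names the category."""

    def __init__(self, category: str, placed: int, requested: int, retries: int):
        self.category = category
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"could not place variant category {category!r}: placed {placed} of "
            f"{requested} after {retries} retries per variant; genome too small "
            f"or too crowded"
        )


class PoolExhaustedError(DataError):
    """A read pool does not hold enough reads for the requested draw."""

    def __init__(self, source: str, requested: int, available: int):
        self.source = source
        super().__init__(
            f"read pool {source!r} exhausted: requested {requested} read pairs, "
            f"only {available} available"
        )
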