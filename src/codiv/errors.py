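"""Exception hierarchy shared across the pipeline."""


class CodivError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(CodivError):
    """A file could not be parsed (malformed FASTA/TSV/newick)."""


class SchemaError(CodivError):
    """A table is missing required columns or is empty."""


class ConsistencyError(CodivError):
    """A table violates an internal consistency rule (duplicates, ambiguous maps)."""


class ValidationError(CodivError):
    """A record violates a value-level constraint (alphabet, range, symmetry)."""


class LinkError(CodivError):
    """A cross-reference could not be resolved (e.g. read -> unknown sample)."""


class StateError(CodivError):
    """An operation was called before a prerequisite stage populated its inputs."""


class SaturationError(CodivError):
    """A K2P distance is undefined because the log arguments are non-positive."""


class ConfigError(CodivError):
    """The run configuration is invalid or inconsistent with the data."""
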