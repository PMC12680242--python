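"""Exception hierarchy shared across the toolkit."""


class AttrBenchError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(AttrBenchError):
    """Invalid configuration value (maps to CLI exit code 2)."""


class GenerationError(AttrBenchError):
    """A synthetic-data generator failed to satisfy its constraints."""


class SpecError(AttrBenchError):
    """A requested simulation spec is infeasible (e.g. MAF out of range)."""


class StageError(AttrBenchError):
    """A benchmark stage failed (maps to CLI exit code 3)."""


class SingularFitError(AttrBenchError):
    """Degenerate regression design (e.g. constant covariates)."""
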