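"""Exception types shared across the pipeline."""


class SenescreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SenescreenError, ValueError):
    """A generator or analysis configuration violates its invariants.

    The message names the offending field so misconfigured runs fail loudly
    and early rather than producing silently wrong simulations.
    """


class InputError(SenescreenError, ValueError):
    """An input table, matrix or label vector violates a precondition."""
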