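"""Exception hierarchy.

The CLI maps each class to a distinct exit code, so keep the split between
configuration, compilation, integration and decoding failures.
"""


class DomainCodeError(Exception):
    """Base class for all package errors."""


class ConfigError(DomainCodeError):
    """Bad user configuration (netlist file, CLI arguments, builtin names)."""


class CompileError(DomainCodeError):
    """Netlist cannot be expanded into a well-formed reaction network."""


class SimulationError(DomainCodeError):
    """ODE integration failed or produced an unusable solution."""


class DecodingError(DomainCodeError):
    """Reporter plateaus do not resolve into an unambiguous logic word."""


class DesignError(DomainCodeError):
    """Sequence assignment could not satisfy its constraints."""
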