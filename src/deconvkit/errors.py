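"""Exception hierarchy.

Configuration problems (bad parameters, inconsistent specs) raise
:class:`ConfigurationError`; invalid data fed to a numeric operation raises
:class:`DomainError`. Both derive from ``ValueError`` so callers that do not
care about the distinction can catch the builtin.
"""


class DeconvKitError(ValueError):
    """Base class for all deconvkit errors."""


class ConfigurationError(DeconvKitError):
    """Invalid or inconsistent configuration (modes, parameters, specs)."""


class DomainError(DeconvKitError):
    """Input data outside the mathematical domain of an operation."""


class ValidationError(DeconvKitError):
    """Malformed or inconsistent on-disk inputs."""
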