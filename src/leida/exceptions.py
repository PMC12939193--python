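"""Exception hierarchy for the leida package."""


class LeidaError(Exception):
    """Base class for all leida errors."""


class ConfigurationError(LeidaError, ValueError):
    """A parameter or configuration value violates its contract."""


class ValidationError(LeidaError, ValueError):
    """Input data violate a structural invariant (shape, labels, manifest)."""


class DegenerateSignalError(LeidaError, ValueError):
    """A signal is degenerate for the requested operation (e.g. all-zero
    column, for which the instantaneous phase is undefined)."""


class DegenerateClusteringError(LeidaError, RuntimeError):
    """Clustering is infeasible (e.g. fewer distinct points than clusters)."""
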