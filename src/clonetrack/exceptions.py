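"""Package-wide exception types."""


class ClonetrackError(Exception):
    """Base class for all package errors."""


class ValidationError(ClonetrackError):
    """An input table violates a structural invariant."""


class ConfigurationError(ClonetrackError):
    """A simulation or pipeline configuration is inconsistent."""


class PhylogenyError(ClonetrackError):
    """No phylogenetic tree consistent with the cluster CCFs exists."""
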