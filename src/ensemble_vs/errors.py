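"""Exception hierarchy for the screening toolkit."""


class EnsembleVSError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(EnsembleVSError):
    """Invalid or missing configuration (e.g. no ligand designated)."""


class EmptySiteError(EnsembleVSError):
    """Binding-site extraction produced no residues."""


class GeometryError(EnsembleVSError):
    """Degenerate or mismatched point sets for superposition."""


class InsufficientDataError(EnsembleVSError):
    """Not enough compounds / rows / classes to perform the operation."""
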