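"""Exception hierarchy shared across the pipeline stages."""


class NeopriorError(Exception):
    """Base class for all package errors."""


class ParameterError(NeopriorError, ValueError):
    """A configuration or threshold value is out of its documented range."""


class FormatError(NeopriorError, ValueError):
    """An input file or field does not conform to the documented dialect."""


class EvidenceError(NeopriorError, ValueError):
    """Read evidence is internally inconsistent (e.g. zero total depth)."""


class InsufficientDataError(NeopriorError, ValueError):
    """Too few observations to compute the requested statistic."""


class PairingError(NeopriorError, ValueError):
    """Mutant/wild-type wells do not belong to the same assay context."""


class DesignError(NeopriorError, ValueError):
    """A statistical design is degenerate (e.g. a group with <2 samples)."""


class SignatureError(NeopriorError, ValueError):
    """A gene signature does not overlap the expression matrix."""


class AnnotationError(NeopriorError, ValueError):
    """A candidate lacks annotations required by the ranking policy."""


class ConvergenceError(NeopriorError, RuntimeError):
    """An iterative fit failed to converge within its iteration budget."""


class ConfigError(NeopriorError, ValueError):
    """A pipeline configuration references missing files or bad toggles."""
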