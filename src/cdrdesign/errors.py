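"""Exception hierarchy for the package."""


class CdrDesignError(Exception):
    """Base class for all package errors."""


class FormatError(CdrDesignError):
    """Unparseable or unserializable structure data."""


class AnnotationError(CdrDesignError):
    """Region annotation failed (empty required window, overlap, ...)."""


class DihedralError(CdrDesignError):
    """Dihedral extraction failed (chain break, missing atoms)."""


class MetricError(CdrDesignError):
    """Cluster metric / assignment failure."""


class SchemaError(CdrDesignError):
    """Database table missing mandatory columns."""


class ProfileError(CdrDesignError):
    """Cluster sequence profile construction failure."""


class GraftError(CdrDesignError):
    """Grafting preconditions violated."""


class PaletteError(CdrDesignError):
    """Design palette construction failure."""


class DirectiveError(CdrDesignError):
    """Bad resfile-like override or instruction-file directive."""


class ScoringError(CdrDesignError):
    """Energy evaluation failure."""


class InterfaceError(CdrDesignError):
    """Interface energy undefined (e.g. single-chain complex)."""


class ConfigError(CdrDesignError):
    """Invalid protocol or filter configuration."""


class MetricsError(CdrDesignError):
    """Recovery statistics failure (missing labels, empty sets)."""


class SyntheticSpecError(CdrDesignError):
    """Invalid synthetic benchmark specification."""
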