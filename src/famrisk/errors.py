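"""Exception hierarchy for famrisk."""


class FamriskError(Exception):
    """Base class for all famrisk errors."""


class ParseError(FamriskError, ValueError):
    """A file could not be parsed into the expected records."""


class PedigreeError(FamriskError, ValueError):
    """A pedigree violates structural constraints (cycles, dangling parents...)."""


class ValidationError(FamriskError, ValueError):
    """A record or configuration value violates its invariants."""


class VcfFormatError(ParseError):
    """A VCF lacks required fields or has malformed annotations."""


class ConfigError(FamriskError, ValueError):
    """A run configuration is missing keys or fails schema checks."""


class NoCommonAncestorError(FamriskError, ValueError):
    """The requested individuals have no common ancestral couple."""


class EnumerationBoundError(FamriskError, ValueError):
    """Exact inheritance-vector enumeration would exceed the feasible bound."""
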