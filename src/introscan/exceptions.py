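"""Exception hierarchy shared across the package."""


class IntroscanError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(IntroscanError):
    """Malformed alignment input (unequal lengths, bad residues)."""


class MetadataError(IntroscanError, KeyError):
    """A sequence or locus lacks required metadata."""


class SampleSizeError(IntroscanError):
    """An operation received fewer samples than it requires."""


class JCDomainError(IntroscanError):
    """Raw distance >= 3/4: outside the Jukes-Cantor correction domain."""


class FrameError(IntroscanError):
    """Reading-frame problem (offset beyond sequence, all-stop codon)."""


class ParameterError(IntroscanError, ValueError):
    """A numeric parameter is outside its valid range."""


class StatisticError(IntroscanError):
    """A statistic is undefined on the supplied data."""


class ModelError(IntroscanError):
    """A simulation model produced mostly degenerate output."""
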