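"""Exception hierarchy shared across the pipeline stages."""


class NadcapseqError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NadcapseqError):
    """A parameter or simulation configuration is outside its valid domain."""


class InputError(NadcapseqError):
    """An input value violates an operation's preconditions."""


class FormatError(NadcapseqError):
    """A file is malformed (bad FASTQ/FASTA record, duplicate id, ...)."""


class NormalizationError(NadcapseqError):
    """Size-factor normalization is undefined for the given count matrix."""


class NoJunctionError(NadcapseqError):
    """A read offered for junction calling contains no qualifying polyA run."""


class CoordinateError(NadcapseqError):
    """A transcript coordinate lies outside the transcript bounds."""
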