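"""Exception hierarchy for forensnp."""


class ForensnpError(Exception):
    """Base class for all package errors."""


class ValidationError(ForensnpError):
    """Input data violates a documented contract (malformed file, bad frequencies...)."""


class ParseError(ValidationError):
    """A file could not be parsed; the message names the offending record."""


class UnsupportedLocusError(ValidationError):
    """A locus falls outside supported classes (e.g. >3 alleles, tri-allelic LD)."""


class UndefinedStatisticError(ForensnpError):
    """A statistic is undefined for the given data (e.g. all calls missing)."""


class EmptyResultError(ForensnpError):
    """A filter removed every sample or every locus."""
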