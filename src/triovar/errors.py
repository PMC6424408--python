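"""Exception hierarchy for triovar."""


class TriovarError(Exception):
    """Base class for all triovar errors."""


class VcfFormatError(TriovarError):
    """Malformed VCF input (e.g. records without a GT FORMAT field)."""


class PloidyError(TriovarError):
    """A genotype call with ploidy other than 2 was encountered."""


class ReferenceMismatchError(TriovarError):
    """A variant's REF allele disagrees with the reference sequence."""


class IntervalError(TriovarError):
    """An interval with end < start or start < 1."""


class TranscriptModelError(TriovarError):
    """An inconsistent transcript model (e.g. CDS length not divisible by 3)."""


class ConfigurationError(TriovarError):
    """Invalid pipeline or filter configuration (e.g. trio sample absent)."""


class GenerationError(TriovarError):
    """The synthetic-data generator could not satisfy its constraints."""


class ConsistencyError(TriovarError):
    """Internal consistency violation (e.g. non-monotone cascade counts)."""
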