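"""Exception hierarchy.

Input problems, aligner failures and internal invariant violations are kept
distinct so the CLI can map them to different exit codes.
"""


class IgsimError(Exception):
    """Base class for all igsim errors."""


class InputError(IgsimError):
    """A problem with user-supplied input (FASTA, hit table, config)."""


class EmptyFastaError(InputError):
    pass


class DuplicateIdError(InputError):
    pass


class AlphabetError(InputError):
    pass


class TooFewGenomesError(InputError):
    pass


class ShortGenomeError(InputError):
    pass


class HitTableError(InputError):
    """Malformed precomputed hit table or unknown genome id in it."""


class AlignerError(IgsimError):
    """External aligner missing, failing, or producing unusable output."""


class AlignerNotFoundError(AlignerError):
    pass


class InternalError(IgsimError):
    """An internal invariant was violated; indicates a bug upstream."""
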