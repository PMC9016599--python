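"""Exception hierarchy for entsat."""


class EntsatError(Exception):
    """Base class for all entsat-specific errors."""


class AlignmentFormatError(EntsatError):
    """Malformed alignment input (unequal row lengths, unparsable file)."""


class DuplicateLabelError(AlignmentFormatError):
    """Two sequences in one alignment share a taxon label."""


class EmptyInputError(AlignmentFormatError):
    """Alignment file contains no sequences."""


class UndefinedCompositionError(EntsatError):
    """Base composition requested over a selection with no non-missing states."""


class InsufficientSitesError(EntsatError):
    """Fewer than two usable sites; the t-statistic is undefined."""


class DegenerateVarianceError(EntsatError):
    """Per-site information has zero variance but a nonzero distance to full entropy."""


class InfiniteInformationError(EntsatError):
    """A site contains a nucleotide whose composition probability is zero."""


class NoSharedSitesError(EntsatError):
    """A pair of sequences has no site where both have a non-missing state."""
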