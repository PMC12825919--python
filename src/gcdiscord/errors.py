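"""Exception hierarchy for the gcdiscord pipeline.

Every error raised by the package derives from :class:`GcdiscordError`, so
callers (and the CLI) can distinguish pipeline failures from programming
errors.
"""


class GcdiscordError(Exception):
    """Base class for all gcdiscord errors."""


class UsageError(GcdiscordError):
    """An operation was called with arguments violating its preconditions."""


class ConfigurationError(GcdiscordError):
    """Invalid configuration (overlapping windows, bad tolerances, ...)."""


# --- sequence / alignment I/O ------------------------------------------------

class AlignmentShapeError(GcdiscordError):
    """Sequences in an alignment do not all have the same length."""


class AlphabetError(GcdiscordError):
    """A sequence contains characters outside the declared alphabet."""


class FormatError(GcdiscordError):
    """Malformed input file (duplicate taxon ids, empty labels, ...)."""


class NewickParseError(GcdiscordError):
    """Unparseable Newick data."""


class FrameError(GcdiscordError):
    """CDS length not divisible by three."""


class UnsupportedCodeError(GcdiscordError):
    """Genetic code id outside the supported set {1, 5}."""


class EncodingError(GcdiscordError):
    """A residue cannot be encoded by any codon of the genetic code."""


# --- metrics -----------------------------------------------------------------

class UndefinedCompositionError(GcdiscordError):
    """No countable residues/nucleotides to compute a composition from."""


class DegenerateTreeError(GcdiscordError):
    """Tree with zero total branch length or all-zero patristic distances."""


class MissingSupportError(GcdiscordError):
    """No internal node carries a support value."""


# --- tree comparison / building ---------------------------------------------

class TreeIntegrityError(GcdiscordError):
    """Duplicate tip labels, negative branch lengths, or out-of-range support."""


class InsufficientOverlapError(GcdiscordError):
    """Fewer than four shared taxa between two trees."""


class MissingOverlapError(GcdiscordError):
    """A taxon pair shares no comparable (gap-free) alignment columns."""


class MatrixIntegrityError(GcdiscordError):
    """Non-finite or otherwise invalid distance matrix entries."""


class AdapterError(GcdiscordError):
    """External tree-inference command failed; carries captured diagnostics."""


# --- matching ----------------------------------------------------------------

class DegenerateReferenceError(GcdiscordError):
    """Relative tolerance undefined for a zero-valued reference property."""


class InfeasibleMatchingError(GcdiscordError):
    """Candidate pool smaller than the requested matched-set size."""
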