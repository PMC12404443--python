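"""Exception hierarchy.

Every rejected input gets a distinct exception class so callers (and the
CLI) can tell apart, e.g., a nonsense variant slipping into a missense
table from a merely malformed consequence string.
"""


class ArdscanError(Exception):
    """Base class for all package errors."""


# --- variant tables -------------------------------------------------------

class ConsequenceParseError(ArdscanError):
    """HGVS p. string does not match ``p.<Three><digits><Three>``."""


class UnknownAminoAcidError(ConsequenceParseError):
    """Three-letter code is not one of the 20 canonical amino acids."""


class NotMissenseError(ConsequenceParseError):
    """Consequence is synonymous, nonsense or frameshift, not missense."""


class NumberingOutOfRangeError(ArdscanError):
    """Mapped residue position fell below 1."""


class ReferenceMismatchError(ArdscanError):
    """Two variants disagree on the reference amino acid at one position."""


class EmptySpectrumError(ArdscanError):
    """Operation requires a non-empty variant spectrum."""


# --- structures / SASA ----------------------------------------------------

class StructureReadError(ArdscanError):
    """File could not be parsed as PDB or mmCIF."""


class EmptySelectionError(ArdscanError):
    """Chain/range filter matched no atoms."""


class DegenerateGeometryError(ArdscanError):
    """Two atoms occupy identical coordinates."""


class UnknownResidueError(ArdscanError):
    """Residue type missing from the reference max-ASA table."""


# --- burial profile -------------------------------------------------------

class EmptySeriesError(ArdscanError):
    """Smoothing (or ranking) got an empty series."""


class AlignmentError(ArdscanError):
    """Reference id absent or position beyond the ungapped sequence."""


# --- functional assays ----------------------------------------------------

class MissingReferenceError(ArdscanError):
    """Dose–response table lacks the reference concentration."""


class ZeroReferenceError(ArdscanError):
    """Reference current is zero (or non-positive where positivity is required)."""


class SegmentError(ArdscanError):
    """Requested segment tag missing from a sweep, or no sweeps given."""


class WindowError(ArdscanError):
    """Baseline window does not fit inside the trace."""


class FitError(ArdscanError):
    """Dose–response fit cannot be attempted (too few concentrations)."""


class NoReferenceWindowError(ArdscanError):
    """No sweep falls inside the room-temperature window."""


# --- cell responses -------------------------------------------------------

class NoHealthyCellsError(ArdscanError):
    """Response fraction undefined: zero capsaicin- or ionomycin-responders."""


class DuplicateCellError(ArdscanError):
    """Two traces share one cell id."""


class ZeroControlError(ArdscanError):
    """Control response fraction is zero; normalization undefined."""
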