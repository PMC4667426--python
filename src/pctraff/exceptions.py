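"""Exception hierarchy for the pctraff pipeline.

Each pipeline failure mode has its own class so callers (and the CLI) can
distinguish an empty input from a matrix emptied by filtering from a pair
universe too small to standardize.
"""


class PcTraffError(Exception):
    """Base class for all pctraff errors."""


class FormatError(PcTraffError):
    """Malformed input file (FASTA, TRANSFAC block, hit table)."""


class NoSequencesError(PcTraffError):
    """The sequence set is empty."""


class NoHitsError(PcTraffError):
    """No binding-site hits available (none supplied, none found by scanning)."""


class EmptyMatrixError(PcTraffError):
    """The TFBS-sequence matrix has zero total count."""


class NoSurvivingColumnsError(PcTraffError):
    """Every matrix column was removed by the Phase-1 filters."""


class NoPairsError(PcTraffError):
    """No binding-site pair satisfies the distance constraints."""


class InsufficientPairsError(PcTraffError):
    """Fewer than two observed pair types; z-scores are undefined."""


class PlacementError(PcTraffError):
    """The synthetic generator could not place an insertion without overlap."""
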