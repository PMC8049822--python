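"""Exception hierarchy for redpep.

Every error raised on bad user input derives from :class:`RedpepError`,
so CLI entry points can catch one type and print an actionable message.
"""


class RedpepError(Exception):
    """Base class for all redpep errors."""


class SchemeParseError(RedpepError):
    """Cluster-string notation could not be parsed (illegal character, empty group)."""


class PartitionError(RedpepError):
    """Groups do not form a partition of the 20 standard amino acids."""


class SizeMismatchError(RedpepError):
    """Declared group count disagrees with the parsed notation."""


class CatalogError(RedpepError):
    """Malformed or inconsistent scheme-catalog file."""


class ResidueError(RedpepError):
    """Non-standard residue encountered under unknown_policy='error'."""


class DegenerateSequenceError(RedpepError):
    """Sequence is empty after removing non-standard residues."""


class FastaFormatError(RedpepError):
    """Input is not valid FASTA."""


class EmptyDatasetError(RedpepError):
    """No usable records were read."""


class ShortSequenceError(RedpepError):
    """Sequence shorter than the N-peptide window."""


class EncodingError(RedpepError):
    """Symbol outside the reduced alphabet, or incompatible matrices."""


class EmptyMatrixError(RedpepError):
    """Every sample was excluded during encoding."""


class DegenerateGroupsError(RedpepError):
    """A class has too few samples for the requested statistic."""


class ConfigurationError(RedpepError):
    """Invalid run configuration (empty grid, bad N set, ...)."""


class StratificationError(RedpepError):
    """A class is smaller than the number of cross-validation folds."""


class UndefinedMetricError(RedpepError):
    """Metric undefined because a class is absent from the evaluation."""


class EncodingMismatchError(RedpepError):
    """Prediction input was encoded under a different (scheme, N, features)."""


class SyntheticSpecError(RedpepError):
    """Infeasible synthetic-data specification."""
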