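"""Exception hierarchy for the i-rDNA pre-screening pipeline."""


class IrdnaError(Exception):
    """Base class for all package errors."""


class InvalidKmerError(IrdnaError):
    """A k-mer contains a symbol outside the A/C/G/T alphabet."""


class DegenerateSequenceError(IrdnaError):
    """A sequence is too short or has no ambiguity-free k-mer window."""


class DimensionMismatchError(IrdnaError):
    """Two feature vectors (or a vector and a model) disagree in dimension."""


class InfeasibleClusteringError(IrdnaError):
    """Fewer input vectors than requested clusters."""


class EmptyReferenceError(IrdnaError):
    """The marker reference set is empty."""


class NoTaggedClustersError(IrdnaError):
    """Model building produced zero probable-marker clusters."""


class DegenerateSelectionError(IrdnaError):
    """Overlap requested against an empty closest-cluster set."""


class UndefinedMetricError(IrdnaError):
    """A ratio metric (sensitivity, fold reduction) has a zero denominator."""


class UnknownCladeError(IrdnaError):
    """A requested holdout clade does not exist in the taxonomy."""


class FastaFormatError(IrdnaError):
    """Input is not parseable FASTA."""


class CorruptModelError(IrdnaError):
    """A model file is truncated, version-mismatched, or fails its digest."""


class SpecError(IrdnaError):
    """An invalid parameter combination in a community or run specification."""
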