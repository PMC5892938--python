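"""Exception hierarchy shared across the package."""


class PeakclustError(Exception):
    """Base class for all package-specific errors."""


class IllegalCharacter(PeakclustError):
    """Sequence or structure string contains a character outside its alphabet."""


class UnbalancedStructure(PeakclustError):
    """Dot-bracket string has a surplus '(' or ')'."""


class EmptySequence(PeakclustError):
    """An operation requiring a nonempty sequence received an empty one."""


class AdapterUnavailable(PeakclustError):
    """A requested external folding engine is not installed/registered."""


class FormatError(PeakclustError):
    """Malformed structured-FASTA record (e.g. sequence/structure length mismatch)."""


class UnknownOption(PeakclustError):
    """Graph transformation option outside 1..11."""


class EmptyGraph(PeakclustError):
    """Kernel features requested for a graph with no nodes."""


class EmptyVector(PeakclustError):
    """Similarity requested for an empty feature vector."""


class DimensionMismatch(PeakclustError):
    """Matrix/label dimensions disagree."""


class LengthMismatch(PeakclustError):
    """Truth and prediction label lists differ in length."""


class EmptyCluster(PeakclustError):
    """All members of a cluster were discarded during consensus building."""


class InfeasibleSpec(PeakclustError):
    """A motif spec fixes a base pair to an invalid combination."""


class MissingChrom(PeakclustError):
    """Peak references a chromosome absent from the genome FASTA."""
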