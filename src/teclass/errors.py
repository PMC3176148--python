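"""Exception hierarchy shared across the package."""


class TEClassError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(TEClassError):
    """Malformed or inconsistent multiple sequence alignment."""


class DistanceError(TEClassError):
    """A pairwise distance could not be estimated (e.g. no shared sites)."""


class TreeError(TEClassError):
    """Invalid tree operation (too few taxa, non-binary input, bad outgroup)."""


class PartitionError(TEClassError):
    """Invalid subfamily partition or failed refinement."""


class QuantitationError(TEClassError):
    """Missing or unusable internal standard / peak data."""


class ClusteringError(TEClassError):
    """Degenerate clustering input or failed resampling."""
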