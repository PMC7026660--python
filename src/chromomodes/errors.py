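"""Exception hierarchy shared across the package."""


class ChromomodesError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ChromomodesError):
    """A file violated the expected on-disk format."""


class InvalidSpecError(ChromomodesError):
    """A synthetic-data specification failed validation."""


class DegenerateInputError(ChromomodesError):
    """An input is too small or trivial for the requested operation."""


class DisconnectedGraphError(ChromomodesError):
    """The contact graph has more than one connected component."""


class IncompatibleMapsError(ChromomodesError):
    """Contact maps with mismatched bin tables cannot be combined."""


class AlignmentError(ChromomodesError):
    """Loci/mask alignment between two objects failed."""


class SingularityError(ChromomodesError):
    """Coincident loci make the inverse-distance contact law diverge."""


class EmbeddingError(ChromomodesError):
    """Distance-geometry embedding failed to reach the required fidelity."""


class ContractError(ChromomodesError):
    """A numeric value violated an interface contract (range, normalization)."""
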