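"""Exception hierarchy for the LAAO planning toolkit."""


class LaaoError(Exception):
    """Base class for all toolkit errors."""


class MeshFormatError(LaaoError):
    """A mesh file could not be parsed, or an unsupported format was requested."""


class UnsupportedElementError(MeshFormatError):
    """A mesh file mixes or contains element types the toolkit does not handle."""


class LabelError(LaaoError):
    """A required face-label class is missing or inconsistent."""


class TopologyError(LaaoError):
    """Mesh or centreline topology violates an operation's precondition."""


class PlacementError(LaaoError):
    """A device pose falls outside the admissible anatomical region."""


class RangeError(LaaoError):
    """A parameter (e.g. a geodesic station) is outside its valid range."""


class ConvergenceError(LaaoError):
    """An iterative procedure (field solve, marching) failed to converge."""
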