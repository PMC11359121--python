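"""Exception hierarchy for the scanning pipeline."""


class HerdscanError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(HerdscanError):
    """Array shapes do not match the operation's contract."""


class SchemaError(HerdscanError):
    """A sidecar/manifest document is missing a required field or malformed."""


class ParseError(HerdscanError):
    """A file on disk could not be decoded (e.g. malformed PLY header)."""


class ParameterError(HerdscanError):
    """An operation parameter violates its precondition."""


class ConfigurationError(HerdscanError):
    """Rig or pipeline configuration is invalid."""


class InsufficientPointsError(HerdscanError):
    """Too few points for the requested geometric operation."""


class DegenerateCorrespondenceError(HerdscanError):
    """Registration correspondence set too small to constrain a rigid motion."""


class ConnectivityError(HerdscanError):
    """Pairwise registration graph does not connect every camera to the reference."""


class AmbiguityError(HerdscanError):
    """Pairwise registration graph contains a cycle; chaining would be ambiguous."""


class EmptyClusterError(HerdscanError):
    """Density clustering labelled every point as noise."""


class WatertightnessError(HerdscanError):
    """Reconstructed mesh is not closed."""

    def __init__(self, boundary_edges: int):
        self.boundary_edges = boundary_edges
        super().__init__(f"mesh is not watertight: {boundary_edges} boundary edges")


class StageError(HerdscanError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
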