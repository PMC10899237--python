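"""Exception hierarchy for the prosthesis design pipeline."""


class OcuprostError(Exception):
    """Base class for all pipeline errors."""


class AlignmentDegenerateError(OcuprostError):
    """Marker points are collinear or otherwise unusable for alignment."""


class CorrespondenceError(OcuprostError):
    """Landmark correspondence could not be generated (hole in projection)."""


class InsufficientDataError(OcuprostError):
    """Too few training shapes / patches for a model fit."""


class NoWindowFoundError(OcuprostError):
    """Conformer window surfaces could not be traced in the OCT volume."""


class SocketAreaError(OcuprostError):
    """Extracted socket mask covers less than the minimum admissible area."""


class DetectionFailureError(OcuprostError):
    """Iris/pupil boundary detection found no response above the floor."""


class GeometryError(OcuprostError):
    """A mesh does not satisfy the topological requirements of an operation."""
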