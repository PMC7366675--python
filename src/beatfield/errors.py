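"""Exception hierarchy for beatfield."""


class BeatfieldError(Exception):
    """Base class for all beatfield errors."""


class ValidationError(BeatfieldError):
    """Invalid user input or configuration (nesting, ranges, indices)."""


class ResolutionError(ValidationError):
    """Mesh resolution too coarse to resolve a requested feature."""


class PlacementError(ValidationError):
    """Electrode footprints collide or cannot be placed."""


class ConvergenceError(BeatfieldError):
    """A numerical solve failed to reach the requested residual."""


class DegenerateSolveError(BeatfieldError):
    """A solve produced a degenerate quantity (e.g. ~zero injection current)."""


class FingerprintMismatchError(BeatfieldError):
    """An artifact does not belong to the mesh it is being combined with."""


class StalenessError(BeatfieldError):
    """A pipeline stage artifact was produced under a different configuration."""


class DependencyError(BeatfieldError):
    """A pipeline stage is missing an upstream artifact."""
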