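"""Exception hierarchy for surfaceqtl.

Every error raised deliberately by the package derives from
:class:`SurfaceQTLError`, so callers can catch package failures without
swallowing programming errors.
"""


class SurfaceQTLError(Exception):
    """Base class for all surfaceqtl errors."""


class InvalidArgumentError(SurfaceQTLError, ValueError):
    """An argument is non-finite, out of range, or structurally invalid."""


class DegenerateSurfaceError(SurfaceQTLError):
    """The quadratic part of a surface is parabolic/degenerate (no usable axis)."""


class RankDeficiencyError(SurfaceQTLError):
    """A design matrix does not have full column rank."""


class ModelSpecificationError(SurfaceQTLError):
    """A model input violates its contract (e.g. kinship not positive semi-definite)."""


class MissingDataError(SurfaceQTLError):
    """Required data are missing (e.g. no shared non-missing markers for a pair)."""


class EmptyScanError(SurfaceQTLError):
    """A genome scan has no scannable markers."""


class FormatError(SurfaceQTLError):
    """A data file violates the documented on-disk format."""


class PipelineError(SurfaceQTLError):
    """A pipeline stage failed; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}:{code}] {message}")
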