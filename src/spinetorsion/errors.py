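"""Exception hierarchy.

All toolkit errors derive from :class:`SpineTorsionError`, so callers can
distinguish domain failures (bad annotations, degenerate geometry, broken
study designs) from programming errors.
"""


class SpineTorsionError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(SpineTorsionError):
    """An annotation or measurement file violates the documented schema."""


class DegenerateLandmarkError(SpineTorsionError):
    """Landmark geometry admits no angle (coincident points, zero-length segment)."""


class DegenerateBisectorError(DegenerateLandmarkError):
    """The two lamina directions are antiparallel; the bisector is undefined."""


class ImplausibleLandmarkError(SpineTorsionError):
    """A measured angle falls outside +/-90 deg, anatomically impossible on an axial slice."""


class ParameterError(SpineTorsionError):
    """Simulation or analysis parameters violate their stated constraints."""


class IncompleteDesignError(SpineTorsionError):
    """A repeated-measurement table is missing cells required by the analysis."""


class DegenerateDataError(SpineTorsionError):
    """Data carry no variance where the statistic requires some."""
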