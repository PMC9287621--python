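"""Exception hierarchy for the arcuate pipeline.

Each stage signals its own failure mode so callers (and the CLI, which maps
them to distinct exit codes) can tell "no arcuate present" apart from
"arcuate present but unfittable".
"""


class ArcuateError(Exception):
    """Base class for all pipeline errors."""


class LateralityError(ArcuateError, ValueError):
    """Unknown eye-laterality code (must be 'OD' or 'OS')."""


class DegenerateTrajectoryError(ArcuateError):
    """A trajectory clipped to an empty polyline."""


class NoArcuateError(ArcuateError):
    """No arcuate-shaped abnormal component found in the probability map."""


class DegenerateBorderError(ArcuateError):
    """Too few usable radial bins to define a border pair."""


class NoOverlapError(ArcuateError):
    """Border and trajectory share no radial bin."""


class FitFailureError(ArcuateError):
    """Every candidate initial position failed to overlap the border."""


class DegenerateRegionError(ArcuateError):
    """The two border fits map to a zero-length circumpapillary arc."""
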