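"""Circumpapillary RNFL (cpRNFL) profile analysis.

The circle b-scan around the disc is unwrapped into a TSNIT profile
(temporal-superior-nasal-inferior-temporal, 0..360 deg).  Each position
carries a measured thickness and a normative mean/SD; a position is
classified <=5% or <=1% abnormal when its thickness falls below the
corresponding lower quantile of the per-position normative Gaussian.

The two best-fit border positions of an arcuate delimit a
trajectory-determined arc on this circle; the statistic of interest is
the fraction of that arc classified abnormal at each level — under the
model, damage visible as an arcuate on the p-map should make (close to)
the whole arc abnormal at the 5% level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .errors import DegenerateRegionError
from .fitting import FitResult
from .geometry import tsnit_from_phi, wrap_phi

__all__ = [
    "CpRNFLProfile",
    "AngularRegion",
    "classify_percentile",
    "region_from_fits",
    "fraction_below",
]


@dataclass
class CpRNFLProfile:
    """A TSNIT thickness profile with per-position normative statistics.

    All four arrays are parallel; ``positions`` must be an evenly spaced
    grid whose spacing divides 360 (default acquisition is resampled to
    0.5 deg/position).
    """

    positions: np.ndarray
    thickness: np.ndarray
    norm_mean: np.ndarray
    norm_sd: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.thickness = np.asarray(self.thickness, dtype=float)
        self.norm_mean = np.asarray(self.norm_mean, dtype=float)
        self.norm_sd = np.asarray(self.norm_sd, dtype=float)
        n = len(self.positions)
        if not (len(self.thickness) == len(self.norm_mean) == len(self.norm_sd) == n):
            raise ValueError("profile arrays must have equal length")
        steps = np.diff(self.positions)
        if n < 2 or not np.allclose(steps, steps[0]):
            raise ValueError("positions must be evenly spaced")
        spacing = float(steps[0])
        if not np.isclose(round(360.0 / spacing) * spacing, 360.0):
            raise ValueError("spacing must divide 360 degrees")
        if not (self.norm_sd > 0).all():
            raise ValueError("normative SD must be positive everywhere")

    @property
    def spacing(self) -> float:
        return float(self.positions[1] - self.positions[0])


@dataclass(frozen=True)
class AngularRegion:
    """A wrap-aware arc on the TSNIT circle, from ``start`` increasing
    (mod 360) to ``end``."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not 0.0 < self.length < 360.0:
            raise DegenerateRegionError(
                f"arc length {self.length} outside (0, 360)"
            )

    @property
    def length(self) -> float:
        return (self.end - self.start) % 360.0

    def contains(self, t) -> np.ndarray:
        """Membership test for TSNIT positions (inclusive of both bounds)."""
        off = np.mod(np.asarray(t, dtype=float) - self.start, 360.0)
        return off <= self.length + 1e-9


def classify_percentile(profile: CpRNFLProfile) -> np.ndarray:
    """Per-position category: 0 normal, 1 (<=5%), 2 (<=1%).

    Thresholds come from the per-position normative Gaussian: a position
    is <=1% when thickness < mean + z(0.01)*sd (z(0.01) ~ -2.326), and
    <=5% analogously; <=1% positions are a subset of <=5% positions.
    """
    t1 = profile.norm_mean + norm.ppf(0.01) * profile.norm_sd
    t5 = profile.norm_mean + norm.ppf(0.05) * profile.norm_sd
    cat = np.zeros(len(profile.positions), dtype=int)
    cat[profile.thickness < t5] = 1
    cat[profile.thickness < t1] = 2
    return cat


def region_from_fits(fit_upper: FitResult, fit_lower: FitResult) -> AngularRegion:
    """TSNIT arc bounded by the two borders' best-fit initial positions.

    Both positions lie in the same hemifield (the fits come from the two
    borders of one arcuate), so the within-hemifield arc is simply the
    one running from the smaller to the larger TSNIT position; it never
    crosses the nasal or temporal midline.
    """
    t_u = tsnit_from_phi(wrap_phi(fit_upper.phi0_best))
    t_l = tsnit_from_phi(wrap_phi(fit_lower.phi0_best))
    if np.isclose(t_u, t_l):
        raise DegenerateRegionError("coincident border fits bound no region")
    return AngularRegion(min(t_u, t_l), max(t_u, t_l))


def fraction_below(
    profile: CpRNFLProfile, region: AngularRegion, level: int
) -> float:
    """Fraction of the region's angular measure abnormal at ``level``.

    ``level`` is 5 (counts <=5% and <=1% positions) or 1 (<=1% only);
    positions are weighted equally.
    """
    if level not in (5, 1):
        raise ValueError("level must be 5 or 1")
    sel = region.contains(profile.positions)
    if not sel.any():
        raise ValueError("region covers no profile position")
    cat = classify_percentile(profile)[sel]
    need = 1 if level == 5 else 2
    return float(np.mean(cat >= need))
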