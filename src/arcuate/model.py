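"""The arcuate model: retinal nerve fiber bundle trajectories.

A bundle leaving the optic nerve head at initial angle ``phi0`` (plain
polar about the ONH center, degrees) follows

    phi(phi0, r) = phi0 + b(phi0) * (r - r0) ** c(phi0)

where ``c`` locates the curvature along the path and ``b`` sets its
amount.  Both are sector-specific hyperbolic-tangent forms of ``phi0``;
``b`` additionally depends on a curvature-magnitude parameter ``beta``
(``beta_sup`` superior, ``beta_inf`` inferior) whose empirical ranges are
[-2.5, -1.3] and [0.1, 1.3] with means -1.90 and 0.70.  Superior bundles
(60 <= phi0 <= 180) curve counterclockwise toward the temporal raphe
(b > 0); inferior bundles (-180 < phi0 <= -60) curve clockwise (b < 0);
nasal bundles (-60 < phi0 < 60) are approximated as straight radial rays
off the circle b-scan.

Trajectories are computed in a model frame with the fovea at the origin
and the ONH center at (15, 2) deg under an assumed fovea-disc (FD) angle
of -7.59 deg, then mapped onto an individual scan by (a) starting at the
circle b-scan radius r_c (so r0 = r_c), (b) rotating about the fovea by
the relative FD angle (recorded minus assumed), (c) translating the ONH
onto the recorded BMO center, and (d) clipping at the rotated horizontal
line through the fovea (the temporal raphe / FD-line boundary) or at the
scan field edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import DegenerateTrajectoryError
from .geometry import PointDeg, ScanGeometry, wrap_phi

__all__ = [
    "BETA_SUP_RANGE",
    "BETA_INF_RANGE",
    "BETA_SUP_MEAN",
    "BETA_INF_MEAN",
    "BundleModelParams",
    "Trajectory",
    "Region",
    "c_sup",
    "c_inf",
    "b_sup",
    "b_inf",
    "phi_of_r",
    "region_of_phi0",
    "beta_grid",
    "sample_trajectory",
]

Region = Literal["superior", "inferior", "nasal"]

# Empirical parameter ranges and means, ordered as conventionally printed
# (first endpoint first in the 11-value grid).
BETA_SUP_RANGE = (-1.3, -2.5)
BETA_INF_RANGE = (1.3, 0.1)
BETA_SUP_MEAN = -1.90
BETA_INF_MEAN = 0.70


@dataclass(frozen=True)
class BundleModelParams:
    """Configuration of the trajectory model.

    Attributes
    ----------
    r0_default : float
        Initial radius of the original model formulation (deg); retained
        for reference — on scans r0 is taken as the circle radius r_c.
    onh_assumed : PointDeg
        Assumed ONH eccentricity in the model frame (deg).
    fd_assumed_deg : float
        Assumed fovea-disc angle of the model frame (deg, right eye).
    r_step_deg : float
        Radial sampling step (deg); sub-pixel relative to 0.25 deg/px maps.
    r_max_deg : float
        Radial cutoff (deg); covers the 30 x 25 deg scan field.
    field_extent_deg : tuple or None
        Optional (width, height) of a fovea-centered clipping box, deg.
        None (default) disables field-edge truncation: the disc sits at
        the nasal edge of the macula-centered raster, so the circle scan
        itself extends beyond a 30-deg-wide box and trajectories are then
        bounded by ``r_max_deg`` alone.
    allow_beta_outside : bool
        Permit beta values outside the empirical ranges.
    """

    r0_default: float = 4.0
    onh_assumed: PointDeg = PointDeg(15.0, 2.0)
    fd_assumed_deg: float = -7.59
    r_step_deg: float = 0.05
    r_max_deg: float = 25.0
    field_extent_deg: tuple[float, float] | None = None
    allow_beta_outside: bool = False

    def __post_init__(self) -> None:
        if not self.r_step_deg > 0:
            raise ValueError("r_step_deg must be positive")
        if not self.r_max_deg > self.r0_default:
            raise ValueError("r_max_deg must exceed r0_default")


@dataclass
class Trajectory:
    """One sampled fiber-bundle path in the normalized scan frame.

    ``polyline`` is an (N, 2) array of scan-frame points (deg); ``r`` and
    ``phi`` give the same samples in polar form about the BMO center, with
    ``phi`` kept on a continuous (unwrapped) branch starting near phi0.
    """

    phi0: float
    beta: float | None
    region: Region
    polyline: np.ndarray
    r: np.ndarray
    phi: np.ndarray
    clip_reason: Literal["raphe", "fd_line", "field_edge", "none"]

    @property
    def phi0_external(self) -> float:
        """phi0 with inferior angles reported in [180, 300]."""
        return self.phi0 + 360.0 if self.region == "inferior" else self.phi0


def region_of_phi0(phi0: float) -> Region:
    """Retinal sector of an initial angle (wrapped to (-180, 180])."""
    p = wrap_phi(phi0)
    if 60.0 <= p <= 180.0:
        return "superior"
    if p <= -60.0:
        return "inferior"
    return "nasal"


def _check_sector(phi0, lo: float, hi: float, name: str) -> np.ndarray:
    p = np.asarray(phi0, dtype=float)
    if np.any(p < lo) or np.any(p > hi):
        raise ValueError(f"phi0 outside the {name} sector [{lo}, {hi}]")
    return p


def c_sup(phi0):
    """Curvature-location function for the superior sector (60..180 deg)."""
    p = _check_sector(phi0, 60.0, 180.0, "superior")
    out = 1.9 + 1.4 * np.tanh((p - 121.0) / 14.0)
    return float(out) if np.ndim(phi0) == 0 else out


def c_inf(phi0):
    """Curvature-location function for the inferior sector (-180..-60 deg)."""
    p = _check_sector(phi0, -180.0, -60.0, "inferior")
    out = 1.0 + 0.5 * np.tanh((-p - 90.0) / 25.0)
    return float(out) if np.ndim(phi0) == 0 else out


def _check_beta(beta: float, rng: tuple[float, float], allow: bool, name: str) -> None:
    lo, hi = sorted(rng)
    if not allow and not (lo <= beta <= hi):
        raise ValueError(
            f"{name}={beta} outside the empirical range [{lo}, {hi}]; "
            "pass allow_beta_outside=True to override"
        )


def b_sup(phi0, beta_sup: float, *, allow_outside: bool = False):
    """Curvature-amount function, superior sector; strictly positive."""
    p = _check_sector(phi0, 60.0, 180.0, "superior")
    _check_beta(beta_sup, BETA_SUP_RANGE, allow_outside, "beta_sup")
    out = np.exp(beta_sup + 3.9 * np.tanh(-(p - 121.0) / 14.0))
    return float(out) if np.ndim(phi0) == 0 else out


def b_inf(phi0, beta_inf: float, *, allow_outside: bool = False):
    """Curvature-amount function, inferior sector; strictly negative."""
    p = _check_sector(phi0, -180.0, -60.0, "inferior")
    _check_beta(beta_inf, BETA_INF_RANGE, allow_outside, "beta_inf")
    out = -np.exp(beta_inf + 1.5 * np.tanh(-(-p - 90.0) / 25.0))
    return float(out) if np.ndim(phi0) == 0 else out


def phi_of_r(phi0, r, r0: float, beta: float, region: Region, *, allow_beta_outside=False):
    """Evaluate the trajectory equation phi = phi0 + b * (r - r0) ** c.

    At r = r0 this returns phi0 exactly.  ``r`` may be an array.
    """
    rr = np.asarray(r, dtype=float)
    if np.any(rr < r0):
        raise ValueError("r must be >= r0")
    if region == "superior":
        b = b_sup(phi0, beta, allow_outside=allow_beta_outside)
        c = c_sup(phi0)
    elif region == "inferior":
        b = b_inf(phi0, beta, allow_outside=allow_beta_outside)
        c = c_inf(phi0)
    else:
        raise ValueError("phi_of_r applies to the superior and inferior sectors")
    out = phi0 + b * (rr - r0) ** c
    return float(out) if np.ndim(r) == 0 else out


def beta_grid(region: Region) -> np.ndarray:
    """The 11 evenly spaced beta values of a sector, in printed order.

    Superior: -1.3 .. -2.5 (middle element -1.90, the empirical mean);
    inferior: 1.3 .. 0.1 (middle element 0.70).
    """
    if region == "superior":
        return np.linspace(*BETA_SUP_RANGE, 11)
    if region == "inferior":
        return np.linspace(*BETA_INF_RANGE, 11)
    raise ValueError("beta grids exist for the superior and inferior sectors only")


def sample_trajectory(
    geometry: ScanGeometry,
    phi0: float,
    beta: float | None,
    params: BundleModelParams = BundleModelParams(),
) -> Trajectory:
    """Sample one trajectory on a (right-eye-normalized) scan.

    The path starts on the circle b-scan (r = r_c about the BMO center)
    and is traced outward in steps of ``r_step_deg`` until it reaches
    ``r_max_deg``, leaves the scan field, or crosses the rotated
    fovea-latitude line (raphe on the temporal side of the fovea, FD line
    otherwise); the crossing point itself is added by linear interpolation.

    Raises
    ------
    DegenerateTrajectoryError
        If clipping leaves an empty polyline.
    ValueError
        If r_c >= r_max or the laterality frame is not normalized.
    """
    phi0 = wrap_phi(phi0)
    region = region_of_phi0(phi0)
    r_c = geometry.r_c_deg
    if r_c >= params.r_max_deg:
        raise ValueError("circle radius r_c must be below r_max_deg")

    # Model-frame samples: fovea at origin, ONH at onh_assumed, r0 = r_c.
    r = np.arange(r_c, params.r_max_deg + 0.5 * params.r_step_deg, params.r_step_deg)
    if region == "nasal":
        phi_m = np.full_like(r, phi0)  # straight ray, perpendicular to the circle
    else:
        phi_m = phi_of_r(
            phi0, r, r_c, beta, region, allow_beta_outside=params.allow_beta_outside
        )
    ox, oy = params.onh_assumed
    a = np.radians(phi_m)
    xm = ox + r * np.cos(a)
    ym = oy + r * np.sin(a)

    # Raphe / FD-line clipping happens at the fovea-latitude line, which in
    # the model frame is y = 0; the rigid scan transform below carries the
    # line along, so clipping commutes with it.
    sign0 = np.sign(ym[0])
    if sign0 == 0.0:
        raise DegenerateTrajectoryError("trajectory starts on the boundary line")
    off = ym * sign0 < 0.0
    cross_idx = int(np.argmax(off)) if off.any() else None

    cross_pt = None
    clip_reason: str = "none"
    if cross_idx is not None:
        if cross_idx == 0:  # cannot happen with sign0 != 0, defensive
            raise DegenerateTrajectoryError("empty polyline after clipping")
        i0, i1 = cross_idx - 1, cross_idx
        t = ym[i0] / (ym[i0] - ym[i1])
        cross_pt = (xm[i0] + t * (xm[i1] - xm[i0]), 0.0)
        clip_reason = "raphe" if cross_pt[0] < 0.0 else "fd_line"
        xm, ym, r, phi_m = xm[:i1], ym[:i1], r[:i1], phi_m[:i1]

    # Scan transform: rotate about the model fovea (origin) by the relative
    # FD angle, then translate the rotated ONH onto the recorded BMO center.
    delta = geometry.fd_angle_deg - params.fd_assumed_deg
    da = np.radians(delta)
    ca, sa = np.cos(da), np.sin(da)
    tx = geometry.bmo_center.x - (ca * ox - sa * oy)
    ty = geometry.bmo_center.y - (sa * ox + ca * oy)
    xs = ca * xm - sa * ym + tx
    ys = sa * xm + ca * ym + ty

    if cross_pt is not None:
        cx, cy = cross_pt
        xs = np.append(xs, ca * cx - sa * cy + tx)
        ys = np.append(ys, sa * cx + ca * cy + ty)
        r = np.append(r, np.hypot(cx - ox, cy - oy))
        phi_c = np.degrees(np.arctan2(cy - oy, cx - ox))
        prev = phi_m[-1] if phi_m.size else phi0
        phi_m = np.append(phi_m, prev + wrap_phi(phi_c - prev))

    # Optional field-edge truncation (no interpolated point; the raster
    # simply ends).  Leading samples outside the box are kept so the
    # polyline still starts on the circle; only the outward tail is cut.
    if params.field_extent_deg is not None:
        fx, fy = geometry.fovea
        hw = params.field_extent_deg[0] / 2.0
        hh = params.field_extent_deg[1] / 2.0
        inside = (np.abs(xs - fx) <= hw + 1e-9) & (np.abs(ys - fy) <= hh + 1e-9)
        if not inside.any():
            raise DegenerateTrajectoryError("trajectory never enters the field")
        first_in = int(np.argmax(inside))
        out_tail = np.nonzero(~inside[first_in:])[0]
        if out_tail.size:
            cut = first_in + int(out_tail[0])
            xs, ys, r, phi_m = xs[:cut], ys[:cut], r[:cut], phi_m[:cut]
            clip_reason = "field_edge"

    if xs.size == 0:
        raise DegenerateTrajectoryError("empty polyline after clipping")

    return Trajectory(
        phi0=phi0,
        beta=None if region == "nasal" else float(beta),
        region=region,
        polyline=np.column_stack([xs, ys]),
        r=r,
        phi=phi_m + delta,  # scan-frame angle about the BMO center
        clip_reason=clip_reason,  # type: ignore[arg-type]
    )
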