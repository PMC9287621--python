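"""Coordinate frames and angle conventions for macula-centered OCT scans.

All positions are expressed in degrees of visual angle in a fovea-centered
cartesian frame with +x pointing nasally (toward the optic disc) and +y
superior, in the right-eye convention.  Left-eye (OS) scans are mirrored
into this frame before any modelling (``normalize_to_right_eye``).

Angular positions around the optic nerve head (ONH) use plain polar
coordinates about the Bruch's membrane opening (BMO) center: ``phi = 0``
points nasally (away from the fovea), counterclockwise positive, so the
superior pole is +90 deg and the temporal raphe sits at +/-180 deg.  Two
further angular indexings are provided: clock hours (12 = superior,
3 = nasal, 6 = inferior, 9 = temporal) and the unwrapped TSNIT position
(temporal-superior-nasal-inferior-temporal, 0..360 deg) used to index
circumpapillary thickness profiles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .errors import LateralityError

__all__ = [
    "PointDeg",
    "OnhPolar",
    "ScanGeometry",
    "wrap_phi",
    "normalize_to_right_eye",
    "mirror_point",
    "rotate_about",
    "onh_polar_from_cart",
    "cart_from_onh_polar",
    "clock_hour_from_phi",
    "phi_from_clock_hour",
    "tsnit_from_phi",
    "phi_from_tsnit",
]


class PointDeg(NamedTuple):
    """A point in degrees of visual angle (fovea-centered, right-eye frame)."""

    x: float
    y: float


class OnhPolar(NamedTuple):
    """Polar position about the ONH center: radius (deg) and angle phi.

    ``phi`` is stored wrapped to (-180, 180] with 0 = nasal, CCW positive.
    """

    r: float
    phi: float


@dataclass(frozen=True)
class ScanGeometry:
    """Per-eye anatomical frame of one OCT acquisition.

    Parameters
    ----------
    fovea : PointDeg
        Fovea center; the frame origin after normalization.
    bmo_center : PointDeg
        BMO (disc) center. Positive x in the normalized frame.
    fd_angle_deg : float
        Fovea-disc axis angle recorded by the instrument, degrees.
    r_c_deg : float
        Radius of the circle b-scan, degrees of visual angle.
    laterality : str
        'OD' (right) or 'OS' (left).
    """

    fovea: PointDeg = PointDeg(0.0, 0.0)
    bmo_center: PointDeg = PointDeg(15.0, 2.0)
    fd_angle_deg: float = -7.59
    r_c_deg: float = 6.0
    laterality: str = "OD"

    def __post_init__(self) -> None:
        if self.laterality not in ("OD", "OS"):
            raise LateralityError(f"unknown laterality {self.laterality!r}")
        if not self.r_c_deg > 0:
            raise ValueError("circle-scan radius r_c must be positive")

    def to_dict(self) -> dict:
        return {
            "fovea_xy_deg": [self.fovea.x, self.fovea.y],
            "bmo_center_xy_deg": [self.bmo_center.x, self.bmo_center.y],
            "fd_angle_deg": self.fd_angle_deg,
            "r_c_deg": self.r_c_deg,
            "laterality": self.laterality,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        return cls(
            fovea=PointDeg(*d["fovea_xy_deg"]),
            bmo_center=PointDeg(*d["bmo_center_xy_deg"]),
            fd_angle_deg=float(d["fd_angle_deg"]),
            r_c_deg=float(d["r_c_deg"]),
            laterality=str(d["laterality"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ScanGeometry":
        return cls.from_dict(json.loads(Path(path).read_text()))


def wrap_phi(phi):
    """Wrap an angle (degrees) into (-180, 180]. Works on scalars and arrays."""
    w = np.mod(phi, 360.0)
    w = np.where(w > 180.0, w - 360.0, w)
    return float(w) if np.ndim(phi) == 0 else w


def mirror_point(p: PointDeg) -> PointDeg:
    """Mirror across the vertical (x = 0) axis: the OS <-> OD flip."""
    return PointDeg(-p.x, p.y)


def normalize_to_right_eye(
    geometry: ScanGeometry, points: Sequence[PointDeg] = ()
) -> tuple[ScanGeometry, list[PointDeg]]:
    """Bring a scan (and optional extra points) into the right-eye frame.

    OS inputs are mirrored across the vertical axis (x -> -x) and the FD
    angle sign is flipped (mirroring reverses angular orientation); OD
    inputs are returned unchanged.  The stored laterality is preserved so
    the original eye remains identifiable.
    """
    if geometry.laterality == "OD":
        return geometry, list(points)
    if geometry.laterality != "OS":
        raise LateralityError(f"unknown laterality {geometry.laterality!r}")
    geom = replace(
        geometry,
        fovea=mirror_point(geometry.fovea),
        bmo_center=mirror_point(geometry.bmo_center),
        fd_angle_deg=-geometry.fd_angle_deg,
    )
    return geom, [mirror_point(p) for p in points]


def rotate_about(p: PointDeg, center: PointDeg, angle_deg: float) -> PointDeg:
    """Rigid rotation of ``p`` about ``center``, counterclockwise positive."""
    a = math.radians(angle_deg)
    dx, dy = p.x - center.x, p.y - center.y
    ca, sa = math.cos(a), math.sin(a)
    return PointDeg(center.x + ca * dx - sa * dy, center.y + sa * dx + ca * dy)


def onh_polar_from_cart(p: PointDeg, onh_center: PointDeg) -> OnhPolar:
    """Polar coordinates of ``p`` about the ONH center (phi = 0 nasal)."""
    dx, dy = p.x - onh_center.x, p.y - onh_center.y
    r = math.hypot(dx, dy)
    if r == 0.0:
        raise ValueError("point coincides with the ONH center: phi undefined")
    return OnhPolar(r, wrap_phi(math.degrees(math.atan2(dy, dx))))


def cart_from_onh_polar(polar: OnhPolar, onh_center: PointDeg) -> PointDeg:
    """Inverse of :func:`onh_polar_from_cart`."""
    a = math.radians(polar.phi)
    return PointDeg(
        onh_center.x + polar.r * math.cos(a), onh_center.y + polar.r * math.sin(a)
    )


def clock_hour_from_phi(phi):
    """Map ONH angle phi (deg) to a real-valued clock hour in (0, 12].

    Superior (+90) -> 12, nasal (0) -> 3, inferior (-90) -> 6,
    temporal (180) -> 9, in the right-eye frame.  Hours advance clockwise
    (30 deg per hour); the multiple of 12 is chosen so the result lies in
    (0, 12], with the superior pole reported as 12 rather than 0.
    """
    ch = np.mod((90.0 - np.asarray(phi, dtype=float)) / 30.0, 12.0)
    ch = np.where(ch == 0.0, 12.0, ch)
    return float(ch) if np.ndim(phi) == 0 else ch


def phi_from_clock_hour(clock_hour):
    """Inverse of :func:`clock_hour_from_phi`; result wrapped to (-180, 180]."""
    return wrap_phi(90.0 - 30.0 * np.asarray(clock_hour, dtype=float))


def tsnit_from_phi(phi):
    """ONH angle phi -> TSNIT profile position in [0, 360).

    Temporal (phi = 180) -> 0, superior -> 90, nasal -> 180, inferior -> 270.
    """
    t = np.mod(180.0 - np.asarray(phi, dtype=float), 360.0)
    return float(t) if np.ndim(phi) == 0 else t


def phi_from_tsnit(t):
    """Inverse of :func:`tsnit_from_phi`; result wrapped to (-180, 180]."""
    return wrap_phi(180.0 - np.asarray(t, dtype=float))
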