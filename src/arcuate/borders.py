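"""Arcuate-border extraction from RNFL probability maps.

The probability map flags pixels whose RNFL thickness falls below
normative percentiles.  An arcuate defect shows up as an arc-shaped
region of <=1% pixels sweeping from the disc around the macula.  The
extraction pipeline is:

1. binarize: <=1% -> 1, everything else (including outside-field) -> 0;
2. select the arcuate-shaped connected component (by seed point, or the
   largest component with sufficient angular extent about the BMO center);
3. reduce the component to its perimeter pixels;
4. split the perimeter into the two border curves (upper / lower) by
   taking, within each radial bin about the BMO center, the extreme
   angular positions.

Steps 2 and 4 automate what is otherwise manual curation; an explicit
region-of-interest mask can be intersected beforehand to reproduce hand
curation exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import DegenerateBorderError, NoArcuateError
from .geometry import OnhPolar, PointDeg, ScanGeometry, mirror_point, wrap_phi

__all__ = [
    "CAT_NORMAL",
    "CAT_P5",
    "CAT_P1",
    "CAT_OUTSIDE",
    "PMap",
    "BinaryMask",
    "ArcuateBorder",
    "binarize_pmap",
    "select_arcuate_component",
    "extract_perimeter",
    "split_borders",
    "extract_arcuate_borders",
    "unwrap_hemifield",
    "mirror_pmap",
]

# Percentile category codes of the probability map raster.
CAT_NORMAL = 0
CAT_P5 = 1
CAT_P1 = 2
CAT_OUTSIDE = 255


@dataclass
class PMap:
    """Georeferenced raster of percentile categories.

    ``grid[i, j]`` holds a category code; the center of pixel (0, 0) is at
    ``origin`` and pixel (i, j) is at ``origin + (j*pixel_size,
    -i*pixel_size)`` — row 0 is the superior edge of the field.
    """

    grid: np.ndarray
    pixel_size: float
    origin: PointDeg
    geometry: ScanGeometry

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("pmap grid must be 2-D")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        bad = ~np.isin(self.grid, [CAT_NORMAL, CAT_P5, CAT_P1, CAT_OUTSIDE])
        if bad.any():
            raise ValueError("pmap grid contains unknown category codes")

    def pixel_center(self, i, j) -> tuple[np.ndarray, np.ndarray]:
        """Scan-frame coordinates (deg) of pixel centers (vectorized)."""
        x = self.origin.x + np.asarray(j) * self.pixel_size
        y = self.origin.y - np.asarray(i) * self.pixel_size
        return x, y

    def point_to_pixel(self, p: PointDeg) -> tuple[int, int]:
        """Nearest pixel indices for a scan-frame point."""
        j = int(round((p.x - self.origin.x) / self.pixel_size))
        i = int(round((self.origin.y - p.y) / self.pixel_size))
        return i, j


@dataclass
class BinaryMask:
    """A {0,1} raster aligned with its source probability map."""

    grid: np.ndarray
    pmap: PMap

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.uint8)
        if self.grid.shape != self.pmap.grid.shape:
            raise ValueError("mask shape must match the source pmap")
        if not np.isin(self.grid, [0, 1]).all():
            raise ValueError("mask values must be 0 or 1")


@dataclass
class ArcuateBorder:
    """One border curve of an arcuate pattern, polar about the BMO center.

    ``r`` and ``phi`` are parallel arrays sorted by radius; ``phi`` is
    wrapped to (-180, 180].  ``hemifield`` records which half of the
    retina the source component occupies, which fixes the unwrapping
    branch used when comparing angles across the temporal meridian.
    """

    r: np.ndarray
    phi: np.ndarray
    side: str  # 'upper' (max-phi extreme) or 'lower' (min-phi extreme)
    hemifield: str  # 'superior' or 'inferior'
    source_component_id: int = 0

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.r.shape != self.phi.shape or self.r.ndim != 1:
            raise ValueError("r and phi must be parallel 1-D arrays")
        if len(self.r) < 5:
            raise DegenerateBorderError("a border needs at least 5 points")
        if not (self.r > 0).all():
            raise ValueError("border radii must be positive")

    def __len__(self) -> int:
        return len(self.r)

    @property
    def points(self) -> list[OnhPolar]:
        return [OnhPolar(float(r), float(p)) for r, p in zip(self.r, self.phi)]

    def phi_unwrapped(self) -> np.ndarray:
        return unwrap_hemifield(self.phi, self.hemifield)


def unwrap_hemifield(phi, hemifield: str):
    """Move wrapped angles onto a branch continuous across the raphe.

    Superior-hemifield curves live on (-90, 270] (angles just past the
    temporal meridian become > 180); inferior curves on (-270, 90].
    """
    p = np.asarray(phi, dtype=float)
    if hemifield == "superior":
        out = np.where(p <= -90.0, p + 360.0, p)
    elif hemifield == "inferior":
        out = np.where(p > 90.0, p - 360.0, p)
    else:
        raise ValueError(f"unknown hemifield {hemifield!r}")
    return float(out) if np.ndim(phi) == 0 else out


def binarize_pmap(pmap: PMap) -> BinaryMask:
    """Threshold the map: <=1% pixels -> 1, all others (incl. outside) -> 0."""
    return BinaryMask((pmap.grid == CAT_P1).astype(np.uint8), pmap)


def _component_angular_extent(ii: np.ndarray, jj: np.ndarray, pmap: PMap) -> float:
    """Circular angular extent (deg) of a pixel set about the BMO center."""
    x, y = pmap.pixel_center(ii, jj)
    bx, by = pmap.geometry.bmo_center
    phi = np.degrees(np.arctan2(y - by, x - bx))
    phi = np.sort(np.mod(phi, 360.0))
    if len(phi) == 1:
        return 0.0
    gaps = np.diff(phi)
    wrap_gap = 360.0 - phi[-1] + phi[0]
    return 360.0 - max(gaps.max(initial=0.0), wrap_gap)


def _component_hemifield(ii: np.ndarray, jj: np.ndarray, pmap: PMap) -> str:
    """Hemifield of a pixel set by its mean vertical direction about the
    BMO center (robust to arcs crossing the temporal meridian)."""
    x, y = pmap.pixel_center(ii, jj)
    bx, by = pmap.geometry.bmo_center
    phi = np.degrees(np.arctan2(y - by, x - bx))
    return "superior" if np.mean(np.sin(np.radians(phi))) >= 0 else "inferior"


def select_arcuate_component(
    mask: BinaryMask,
    seed: PointDeg | None = None,
    *,
    min_angular_extent: float = 20.0,
    hemifield: str | None = None,
) -> BinaryMask:
    """Keep a single 8-connected component of the binary mask.

    With a ``seed`` point, the component containing it is kept.  Without,
    the largest-area component whose angular extent about the BMO center
    exceeds ``min_angular_extent`` (default 20 deg) is kept — an automated
    stand-in for manually discarding non-arcuate abnormal regions.
    Components reaching the circle scan (within 1.5 deg of r_c) are
    preferred: arcuate patterns emanate from the disc, whereas detached
    fragments near the temporal raphe are field-truncated continuations.
    ``hemifield`` ('superior'/'inferior') restricts the seedless search to
    components of that hemifield.

    Raises
    ------
    NoArcuateError
        If the mask is empty, the seed misses every component, or no
        component is sufficiently arc-shaped.
    """
    labels = measure.label(mask.grid, connectivity=2)
    n = labels.max()
    if n == 0:
        raise NoArcuateError("binary mask is empty")
    if seed is not None:
        i, j = mask.pmap.point_to_pixel(seed)
        if not (0 <= i < labels.shape[0] and 0 <= j < labels.shape[1]):
            raise NoArcuateError("seed point lies outside the raster")
        lab = labels[i, j]
        if lab == 0:
            raise NoArcuateError("seed point is not inside any component")
    else:
        pmap = mask.pmap
        bx, by = pmap.geometry.bmo_center
        lab, best_key = 0, (-1, -1)
        for k in range(1, n + 1):
            ii, jj = np.nonzero(labels == k)
            if hemifield is not None and (
                _component_hemifield(ii, jj, mask.pmap) != hemifield
            ):
                continue
            if _component_angular_extent(ii, jj, mask.pmap) <= min_angular_extent:
                continue
            x, y = pmap.pixel_center(ii, jj)
            reaches_circle = int(
                np.hypot(x - bx, y - by).min() <= pmap.geometry.r_c_deg + 1.5
            )
            key = (reaches_circle, len(ii))
            if key > best_key:
                lab, best_key = k, key
        if lab == 0:
            raise NoArcuateError(
                f"no component with angular extent > {min_angular_extent} deg"
            )
    return BinaryMask((labels == lab).astype(np.uint8), mask.pmap)


def extract_perimeter(mask: BinaryMask) -> BinaryMask:
    """Keep pixels with at least one zero 4-neighbor (or on the raster edge)."""
    cross = ndimage.generate_binary_structure(2, 1)
    interior = ndimage.binary_erosion(mask.grid, structure=cross, border_value=0)
    return BinaryMask(mask.grid & ~interior.astype(np.uint8), mask.pmap)


def split_borders(
    perimeter: BinaryMask,
    *,
    bin_width: float = 0.25,
    component_id: int = 0,
    fd_assumed_deg: float = -7.59,
) -> tuple[ArcuateBorder, ArcuateBorder]:
    """Split a component perimeter into its upper and lower border curves.

    Perimeter pixels are converted to polar coordinates about the BMO
    center and grouped into radial bins of ``bin_width`` (matching the
    fitting quantization).  In each bin the maximum-angle pixel goes to
    the *upper* border and the minimum-angle pixel to the *lower* border;
    bins whose two extremes lie within one pixel of each other (the radial
    end-caps of the arc, or a locally single-pixel-wide arc) are dropped.

    Perimeter pixels on the raster boundary, or adjacent to outside-field
    pixels, are discarded first: there the component is truncated by the
    scanned field, so its outline follows the field edge rather than the
    defect border.  Pixels within one pixel of the rotated fovea-latitude
    line are discarded for the same reason: defects terminate against the
    temporal raphe / FD boundary, whose outline is anatomy rather than an
    arcuate border.  Both rules are the automated analogue of manually
    trimming non-arcuate border segments (``fd_assumed_deg`` is the
    model-frame fovea-disc angle fixing the line's rotation).

    Returns (upper, lower).  Raises :class:`DegenerateBorderError` when
    fewer than 5 usable bins remain.
    """
    pmap = perimeter.pmap
    grid = perimeter.grid.copy()
    # Drop field-truncation outlines: raster edge rows/cols and pixels
    # 4-adjacent to outside-field pixels.
    grid[0, :] = grid[-1, :] = 0
    grid[:, 0] = grid[:, -1] = 0
    outside = pmap.grid == CAT_OUTSIDE
    if outside.any():
        cross = ndimage.generate_binary_structure(2, 1)
        grid[ndimage.binary_dilation(outside, structure=cross)] = 0
    ii, jj = np.nonzero(grid)
    if len(ii) == 0:
        raise NoArcuateError("perimeter mask is empty")
    x, y = pmap.pixel_center(ii, jj)
    # Raphe / FD-line trim: signed distance to the fovea-latitude line
    # rotated by the relative FD angle about the fovea.
    geom = pmap.geometry
    da = np.radians(geom.fd_angle_deg - fd_assumed_deg)
    dist_line = -np.sin(da) * (x - geom.fovea.x) + np.cos(da) * (y - geom.fovea.y)
    keep = np.abs(dist_line) > 1.5 * pmap.pixel_size
    if keep.sum() >= 5:
        ii, jj, x, y = ii[keep], jj[keep], x[keep], y[keep]
    bx, by = pmap.geometry.bmo_center
    r = np.hypot(x - bx, y - by)
    phi_w = wrap_phi(np.degrees(np.arctan2(y - by, x - bx)))
    # Hemifield from the mean vertical direction about the BMO center:
    # robust to arcs that cross the temporal meridian.
    hemifield = "superior" if np.mean(np.sin(np.radians(phi_w))) >= 0 else "inferior"
    phi = unwrap_hemifield(phi_w, hemifield)

    bins = np.floor(r / bin_width).astype(int)
    ups: list[tuple[float, float]] = []
    los: list[tuple[float, float]] = []
    used_bins: list[int] = []
    tol = 1.5 * pmap.pixel_size  # "within one pixel" incl. diagonal neighbors
    r_c = pmap.geometry.r_c_deg
    for k in np.unique(bins):
        if k * bin_width < r_c + bin_width:
            # the ring at the circle edge holds the defect's start cap
            # (the circle arc between the borders), not border pixels
            continue
        sel = np.nonzero(bins == k)[0]
        hi = sel[np.argmax(phi[sel])]
        lo = sel[np.argmin(phi[sel])]
        if np.hypot(x[hi] - x[lo], y[hi] - y[lo]) <= tol:
            continue  # end-cap or single-pixel-wide bin
        ups.append((r[hi], phi[hi]))
        los.append((r[lo], phi[lo]))
        used_bins.append(int(k))
    # The arcuate border is radially contiguous from the circle outward.
    # A large radial gap means the pattern left the scanned field and
    # re-entered elsewhere (e.g. near the temporal raphe): keep only the
    # leading contiguous run (gaps of up to 4 bins = 1 deg are tolerated,
    # e.g. from pinch points or noise).
    n_keep = len(used_bins)
    for i in range(1, len(used_bins)):
        if used_bins[i] - used_bins[i - 1] > 4:
            n_keep = i
            break
    ups, los = ups[:n_keep], los[:n_keep]
    if len(ups) < 5:
        raise DegenerateBorderError(
            f"only {len(ups)} usable radial bins; cannot form a border pair"
        )
    up = np.array(sorted(ups))
    lo = np.array(sorted(los))
    upper = ArcuateBorder(
        up[:, 0], wrap_phi(up[:, 1]), "upper", hemifield, component_id
    )
    lower = ArcuateBorder(
        lo[:, 0], wrap_phi(lo[:, 1]), "lower", hemifield, component_id
    )
    return upper, lower


def extract_arcuate_borders(
    pmap: PMap,
    seed: PointDeg | None = None,
    *,
    roi: np.ndarray | None = None,
    bin_width: float = 0.25,
    min_angular_extent: float = 20.0,
) -> tuple[ArcuateBorder, ArcuateBorder]:
    """Full extraction: binarize -> select -> perimeter -> split.

    ``roi`` is an optional {0,1} raster intersected with the binarized
    map before component selection (manual-curation replacement).
    """
    mask = binarize_pmap(pmap)
    if roi is not None:
        mask = BinaryMask(mask.grid & np.asarray(roi, dtype=np.uint8), pmap)
    comp = select_arcuate_component(
        mask, seed, min_angular_extent=min_angular_extent
    )
    per = extract_perimeter(comp)
    return split_borders(per, bin_width=bin_width)


def mirror_pmap(pmap: PMap) -> PMap:
    """Mirror a probability map across the vertical axis (OS <-> OD).

    Flips the raster left-right, mirrors the geometry (negating the FD
    angle), toggles the stored laterality, and re-anchors the origin so
    georeferencing is preserved.  Involution: applying it twice returns
    an identical map.
    """
    geom = pmap.geometry
    new_geom = replace(
        geom,
        fovea=mirror_point(geom.fovea),
        bmo_center=mirror_point(geom.bmo_center),
        fd_angle_deg=-geom.fd_angle_deg,
        laterality="OS" if geom.laterality == "OD" else "OD",
    )
    ncol = pmap.grid.shape[1]
    new_origin = PointDeg(
        -(pmap.origin.x + (ncol - 1) * pmap.pixel_size), pmap.origin.y
    )
    return PMap(
        grid=np.fliplr(pmap.grid).copy(),
        pixel_size=pmap.pixel_size,
        origin=new_origin,
        geometry=new_geom,
    )
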