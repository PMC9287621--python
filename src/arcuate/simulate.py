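"""Synthetic scans: model-derived arcuate defects with known ground truth.

No public dataset of georeferenced RNFL probability maps exists, so every
pipeline stage is exercised on synthetic eyes whose arcuate defect is
generated *from the trajectory model itself*: the <=1% region is the band
between two trajectories (a known beta and a pair of initial angles),
rasterized onto a Spectralis-like 30 x 25 deg, 0.25 deg/px grid, with an
optional <=5% halo.  The matching cpRNFL profile depresses thickness
below the normative lines over a designed sub-arc of the
trajectory-determined region.  Noise is deliberately simple and fully
seeded: independent pixel flips plus a smooth Gaussian angular jitter of
the defect borders.  Analytic (non-rasterized) borders are also exposed
for exact-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .borders import (
    ArcuateBorder,
    CAT_NORMAL,
    CAT_P1,
    CAT_P5,
    PMap,
    mirror_pmap,
    unwrap_hemifield,
)
from .cprnfl import CpRNFLProfile
from .geometry import PointDeg, ScanGeometry, tsnit_from_phi, wrap_phi
from .model import BundleModelParams, region_of_phi0, sample_trajectory, phi_of_r

__all__ = [
    "NoiseSpec",
    "SimulationSpec",
    "CohortEye",
    "generate_arcuate_pmap",
    "generate_arcuate_borders",
    "generate_cprnfl_profile",
    "generate_cohort",
    "mirror_pmap",
]

# Sub-stream identifiers so each generator draws from its own,
# reproducible stream of the spec seed.
_STREAM_PMAP_JITTER = 0
_STREAM_PMAP_FLIPS = 1
_STREAM_BORDER_JITTER = 2


@dataclass(frozen=True)
class NoiseSpec:
    """Noise knobs: per-pixel flip probability (<=1% <-> normal) and the
    SD (deg) of the smooth angular jitter applied to defect borders."""

    flip_prob: float = 0.0
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be in [0, 1]")
        if self.jitter_sd < 0.0:
            raise ValueError("jitter_sd must be non-negative")


@dataclass(frozen=True)
class SimulationSpec:
    """Ground truth of one synthetic eye.

    ``phi0_pair`` holds the two initial angles (internal convention,
    same hemifield) bounding the defect; ``beta_true`` the generating
    curvature parameter.  All randomness flows from ``seed``.
    """

    beta_true: float
    phi0_pair: tuple[float, float]
    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    pixel_size: float = 0.25
    halo: bool = True
    params: BundleModelParams = field(default_factory=BundleModelParams)

    def __post_init__(self) -> None:
        a, b = (wrap_phi(p) for p in self.phi0_pair)
        if a == b:
            raise ValueError("phi0_pair must hold two distinct angles")
        ra, rb = region_of_phi0(a), region_of_phi0(b)
        if ra != rb or ra == "nasal":
            raise ValueError(
                "phi0_pair must lie in one (superior or inferior) hemifield"
            )
        object.__setattr__(self, "phi0_pair", (a, b))

    @property
    def region(self) -> str:
        return region_of_phi0(self.phi0_pair[0])

    def truth_record(self) -> dict:
        return {
            "beta_true": self.beta_true,
            "phi0_pair": list(self.phi0_pair),
            "phi0_pair_external": [
                p + 360.0 if self.region == "inferior" else p
                for p in self.phi0_pair
            ],
            "region": self.region,
            "seed": self.seed,
            "noise": {
                "flip_prob": self.noise.flip_prob,
                "jitter_sd": self.noise.jitter_sd,
            },
        }


def _smooth_jitter(r_grid: np.ndarray, sd: float, rng: np.random.Generator,
                   n_knots: int = 7) -> np.ndarray:
    """Smooth zero-mean angular perturbation: Gaussian knots spread over
    the radial range, linearly interpolated."""
    if sd == 0.0:
        return np.zeros_like(r_grid)
    knots_r = np.linspace(r_grid[0], r_grid[-1], n_knots)
    knots_v = rng.normal(0.0, sd, n_knots)
    return np.interp(r_grid, knots_r, knots_v)


def _phi_curves(spec: SimulationSpec, rng: np.random.Generator | None,
                r_top: float | None = None):
    """Unclipped model-frame angle curves phi(r) of the two bounding
    trajectories (lower = smaller unwrapped phi0), optionally jittered.
    ``r_top`` extends the radial range past ``r_max_deg`` (rasterization
    needs the curves across the whole field diagonal)."""
    params = spec.params
    r_c = spec.geometry.r_c_deg
    r_grid = np.arange(r_c, (r_top or params.r_max_deg) + 0.5 * params.r_step_deg,
                       params.r_step_deg)
    lo, hi = sorted(spec.phi0_pair)
    curves = []
    for phi0 in (lo, hi):
        phi = phi_of_r(phi0, r_grid, r_c, spec.beta_true, spec.region,
                       allow_beta_outside=params.allow_beta_outside)
        if rng is not None:
            phi = phi + _smooth_jitter(r_grid, spec.noise.jitter_sd, rng)
        curves.append(phi)
    return r_grid, curves[0], curves[1]


def generate_arcuate_pmap(spec: SimulationSpec) -> PMap:
    """Rasterize the band between the two bounding trajectories as <=1%.

    The grid spans the 30 x 25 deg field centered on the fovea (121 x 101
    pixels at the default 0.25 deg/px).  A pixel is part of the defect
    when, mapped into the model frame, it lies between the two bounding
    angle curves at its radius (at or beyond the circle scan) and on the
    defect's side of the fovea-latitude (raphe) line; the defect is
    bounded only by the circle, the raphe and the scanned field, as real
    arcuates are.  An 8-connected two-pixel
    dilation ring becomes the <=5% halo; seeded pixel flips toggle
    <=1% <-> normal.
    """
    geom = spec.geometry
    params = spec.params
    ps = spec.pixel_size
    width, height = 30.0, 25.0
    ncol = int(round(width / ps)) + 1
    nrow = int(round(height / ps)) + 1
    origin = PointDeg(geom.fovea.x - width / 2.0, geom.fovea.y + height / 2.0)

    jit_rng = (
        np.random.default_rng([_STREAM_PMAP_JITTER, spec.seed])
        if spec.noise.jitter_sd > 0 else None
    )
    # Radial range must cover the farthest field corner from the BMO.
    corners_x = np.array([origin.x, origin.x + (ncol - 1) * ps])
    corners_y = np.array([origin.y, origin.y - (nrow - 1) * ps])
    r_top = float(
        max(
            np.hypot(cx - geom.bmo_center.x, cy - geom.bmo_center.y)
            for cx in corners_x
            for cy in corners_y
        )
    ) + 1.0
    r_grid, phi_lo, phi_hi = _phi_curves(spec, jit_rng, r_top)

    jj, ii = np.meshgrid(np.arange(ncol), np.arange(nrow))
    xs = origin.x + jj * ps
    ys = origin.y - ii * ps

    # Invert the scan transform (rotation about the fovea by the relative
    # FD angle, then ONH -> BMO translation) to reach the model frame.
    delta = geom.fd_angle_deg - params.fd_assumed_deg
    da = np.radians(delta)
    ca, sa = np.cos(da), np.sin(da)
    ox, oy = params.onh_assumed
    tx = geom.bmo_center.x - (ca * ox - sa * oy)
    ty = geom.bmo_center.y - (sa * ox + ca * oy)
    xm = ca * (xs - tx) + sa * (ys - ty)
    ym = -sa * (xs - tx) + ca * (ys - ty)

    r_p = np.hypot(xm - ox, ym - oy)
    phi_p = unwrap_hemifield(
        wrap_phi(np.degrees(np.arctan2(ym - oy, xm - ox))), spec.region
    )
    f_lo = np.interp(r_p, r_grid, phi_lo)
    f_hi = np.interp(r_p, r_grid, phi_hi)
    side = ym > 0.0 if spec.region == "superior" else ym < 0.0
    inside = (
        (r_p >= geom.r_c_deg)
        & (phi_p >= f_lo)
        & (phi_p <= f_hi)
        & side
    )

    grid = np.full((nrow, ncol), CAT_NORMAL, dtype=np.uint8)
    if spec.halo:
        halo = ndimage.binary_dilation(
            inside, structure=np.ones((3, 3), bool), iterations=2
        ) & ~inside
        grid[halo] = CAT_P5
    grid[inside] = CAT_P1

    if spec.noise.flip_prob > 0.0:
        rng = np.random.default_rng([_STREAM_PMAP_FLIPS, spec.seed])
        flip = rng.random(grid.shape) < spec.noise.flip_prob
        was_p1 = grid == CAT_P1
        was_norm = grid == CAT_NORMAL
        grid[flip & was_p1] = CAT_NORMAL
        grid[flip & was_norm] = CAT_P1

    return PMap(grid=grid, pixel_size=ps, origin=origin, geometry=geom)


def generate_arcuate_borders(
    spec: SimulationSpec,
) -> tuple[ArcuateBorder, ArcuateBorder]:
    """Analytic borders: the two bounding trajectories' own samples.

    Noise-free these are exact (an RMS fit at the true beta and phi0
    recovers zero residual); with ``jitter_sd`` > 0 a smooth angular
    perturbation is added.  Returns (upper, lower) in the scan frame,
    matching :func:`arcuate.borders.split_borders` conventions.
    """
    lo, hi = sorted(spec.phi0_pair)
    rng = (
        np.random.default_rng([_STREAM_BORDER_JITTER, spec.seed])
        if spec.noise.jitter_sd > 0 else None
    )
    out = {}
    for side, phi0 in (("lower", lo), ("upper", hi)):
        traj = sample_trajectory(spec.geometry, phi0, spec.beta_true, spec.params)
        phi = traj.phi.copy()
        if rng is not None:
            phi += _smooth_jitter(traj.r, spec.noise.jitter_sd, rng)
        out[side] = ArcuateBorder(
            r=traj.r, phi=wrap_phi(phi), side=side, hemifield=spec.region
        )
    return out["upper"], out["lower"]


def generate_cprnfl_profile(
    spec: SimulationSpec,
    abnormal_fraction_design: float = 1.0,
    *,
    spacing: float = 0.5,
    norm_sd_um: float = 10.0,
) -> CpRNFLProfile:
    """A TSNIT profile whose thinning covers a designed fraction of the
    trajectory-determined region.

    The normative mean is a smooth double-hump curve
    ``m(t) = 50 + 45 exp(-((t-90)/45)^2) + 50 exp(-((t-270)/45)^2)`` (um)
    with constant SD; thickness equals the mean everywhere except over
    the leading ``abnormal_fraction_design`` of the arc between the two
    initial angles (mapped to TSNIT), where it is depressed 3.5 SD below
    the mean — beyond the 1% line.  The recovered fraction matches the
    design up to one spacing step per bound.
    """
    if not 0.0 <= abnormal_fraction_design <= 1.0:
        raise ValueError("abnormal_fraction_design must be in [0, 1]")
    positions = np.arange(0.0, 360.0, spacing)
    mean = (
        50.0
        + 45.0 * np.exp(-(((positions - 90.0) / 45.0) ** 2))
        + 50.0 * np.exp(-(((positions - 270.0) / 45.0) ** 2))
    )
    sd = np.full_like(positions, norm_sd_um)
    thickness = mean.copy()
    if abnormal_fraction_design > 0.0:
        t_a, t_b = (tsnit_from_phi(p) for p in spec.phi0_pair)
        t0, t1 = min(t_a, t_b), max(t_a, t_b)
        t_end = t0 + abnormal_fraction_design * (t1 - t0)
        sel = (positions >= t0 - 1e-9) & (positions <= t_end + 1e-9)
        thickness[sel] = mean[sel] - 3.5 * norm_sd_um
    return CpRNFLProfile(positions, thickness, mean, sd)


@dataclass
class CohortEye:
    """One synthetic cohort member: raster, profile, and its ground truth."""

    spec: SimulationSpec
    pmap: PMap
    profile: CpRNFLProfile
    truth: dict


def generate_cohort(
    n: int,
    region: str = "superior",
    beta_true: float | None = None,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    *,
    abnormal_fraction_design: float = 1.0,
    geometry: ScanGeometry | None = None,
) -> list[CohortEye]:
    """Generate ``n`` independent synthetic eyes with recorded truth.

    ``beta_true`` defaults to the sector's empirical mean (-1.90 superior,
    0.70 inferior).  Initial-angle pairs are drawn uniformly: the
    defect's near-horizontal bound 85..110 deg from the nasal ray (its
    mirror image for the inferior retina) and a width of 25..40 deg —
    mid-arcuate defects well inside the scanned field.  Each eye gets its
    own deterministic sub-seed of ``seed``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if region not in ("superior", "inferior"):
        raise ValueError("region must be 'superior' or 'inferior'")
    if beta_true is None:
        beta_true = -1.90 if region == "superior" else 0.70
    rng = np.random.default_rng([9, seed])
    eyes = []
    for k in range(n):
        base = float(rng.uniform(85.0, 110.0))
        width = float(rng.uniform(25.0, 40.0))
        if region == "superior":
            pair = (base, base + width)
        else:
            pair = (-base - width, -base)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = SimulationSpec(
            beta_true=beta_true,
            phi0_pair=pair,
            geometry=geometry or ScanGeometry(),
            noise=noise,
            seed=sub_seed,
        )
        eyes.append(
            CohortEye(
                spec=spec,
                pmap=generate_arcuate_pmap(spec),
                profile=generate_cprnfl_profile(
                    spec, abnormal_fraction_design
                ),
                truth=spec.truth_record(),
            )
        )
    return eyes
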