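"""Normalized root-mean-square fitting of trajectories to arcuate borders.

For each of the 11 grid values of the curvature parameter beta, the
initial angle phi0 is scanned in 0.25-deg steps over the non-nasal range
(60..180 superior, 180..300 inferior, the latter computed internally as
(-180, -60]); for each candidate, border and trajectory are compared as
the RMS of the angular difference between their mean angles within
matched radial bins about the BMO center.  The 11 per-beta minima are
then normalized within the arcuate — z-scores mapped through the
standard normal CDF to percentiles — so arcuates of different sizes can
be pooled into cohort percentile summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .borders import (
    ArcuateBorder,
    PMap,
    binarize_pmap,
    extract_perimeter,
    mirror_pmap,
    select_arcuate_component,
    split_borders,
)
from .errors import (
    DegenerateTrajectoryError,
    FitFailureError,
    NoArcuateError,
    NoOverlapError,
)
from .geometry import PointDeg, ScanGeometry, clock_hour_from_phi, wrap_phi
from .model import BundleModelParams, Trajectory, beta_grid, sample_trajectory

__all__ = [
    "RmsResult",
    "FitResult",
    "BetaSweep",
    "phi0_scan_range",
    "rms_difference",
    "best_fit_phi0",
    "sweep_betas",
    "normalize_rms",
    "cohort_percentile_summary",
    "fit_pmap",
]

PHI0_STEP_DEFAULT = 0.25
BIN_WIDTH_DEFAULT = 0.25


class RmsResult(NamedTuple):
    rms: float
    n_bins: int
    coverage: float


@dataclass(frozen=True)
class FitResult:
    """Best-fitting initial position of one trajectory to one border.

    ``phi0_best`` uses the external convention (inferior angles in
    [180, 300]); ``theta_c_best`` is the same position in clock hours.
    Fits with ``coverage`` below 0.5 (less than half the border's radial
    bins matched by the clipped trajectory) carry ``low_coverage=True``.
    """

    beta: float
    phi0_best: float
    theta_c_best: float
    rms: float
    n_bins_used: int
    coverage: float

    @property
    def phi0_internal(self) -> float:
        return wrap_phi(self.phi0_best)

    @property
    def low_coverage(self) -> bool:
        return self.coverage < 0.5

    def to_dict(self) -> dict:
        return {
            "beta": self.beta,
            "phi0_best": self.phi0_best,
            "theta_c_best": self.theta_c_best,
            "rms": self.rms,
            "n_bins_used": self.n_bins_used,
            "coverage": self.coverage,
        }


@dataclass
class BetaSweep:
    """The 11 per-beta fits of one border plus their normalized percentiles."""

    region: str
    betas: np.ndarray
    results: list[FitResult]
    normalized: np.ndarray
    side: str = ""

    def __post_init__(self) -> None:
        if not (len(self.betas) == len(self.results) == len(self.normalized) == 11):
            raise ValueError("a beta sweep holds exactly 11 entries")

    @property
    def best_beta(self) -> float:
        """Grid beta with the smallest normalized percentile."""
        return float(self.betas[int(np.nanargmin(self.normalized))])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b, res, pct in zip(self.betas, self.results, self.normalized):
            row = {"region": self.region, "side": self.side, "beta": float(b)}
            row.update(res.to_dict() if res is not None else {})
            row["normalized_pct"] = float(pct)
            rows.append(row)
        return pd.DataFrame(rows)


def _bin_means(r: np.ndarray, phi: np.ndarray, bin_width: float):
    """Mean angle per radial bin (bin k covers [k*w, (k+1)*w))."""
    k = np.floor(r / bin_width).astype(np.int64)
    cnt = np.bincount(k)
    sums = np.bincount(k, weights=phi)
    bins = np.nonzero(cnt)[0]
    return bins, sums[bins] / cnt[bins]


def rms_difference(
    border: ArcuateBorder,
    trajectory: Trajectory,
    bin_width: float = BIN_WIDTH_DEFAULT,
) -> RmsResult:
    """Angular RMS difference between a border and a trajectory.

    Both curves are reduced to their mean angle within each radial bin
    about the BMO center; over the bins present in both, the circular
    angular difference (deg) is squared and averaged.  ``coverage`` is
    the matched fraction of the border's bins — bins where the clipped
    trajectory has ended are simply unmatched.

    Raises :class:`NoOverlapError` when no bin is shared.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    bb, bphi = _bin_means(border.r, border.phi_unwrapped(), bin_width)
    tb, tphi = _bin_means(trajectory.r, trajectory.phi, bin_width)
    common, bi, ti = np.intersect1d(bb, tb, return_indices=True)
    if common.size == 0:
        raise NoOverlapError("border and trajectory share no radial bin")
    d = wrap_phi(bphi[bi] - tphi[ti])
    return RmsResult(
        rms=float(np.sqrt(np.mean(np.square(d)))),
        n_bins=int(common.size),
        coverage=float(common.size / bb.size),
    )


def phi0_scan_range(hemifield: str, step: float = PHI0_STEP_DEFAULT) -> np.ndarray:
    """Candidate initial angles (internal convention), excluding the nasal
    sector: superior 60..180 inclusive; inferior (-180, -60] (external
    180..300, of which 180 itself belongs to the superior sector)."""
    if hemifield == "superior":
        return np.arange(60.0, 180.0 + step / 2, step)
    if hemifield == "inferior":
        return np.arange(-180.0 + step, -60.0 + step / 2, step)
    raise ValueError(f"unknown hemifield {hemifield!r}")


def best_fit_phi0(
    border: ArcuateBorder,
    beta: float,
    geometry: ScanGeometry,
    params: BundleModelParams = BundleModelParams(),
    *,
    phi0_step: float = PHI0_STEP_DEFAULT,
    bin_width: float = BIN_WIDTH_DEFAULT,
) -> FitResult:
    """Exhaustive phi0 scan minimizing the RMS difference for one beta.

    Ties are broken toward the smaller phi0 (the scan is ascending and
    only a strictly smaller RMS replaces the incumbent).
    """
    best: tuple[float, RmsResult] | None = None
    for phi0 in phi0_scan_range(border.hemifield, phi0_step):
        try:
            traj = sample_trajectory(geometry, phi0, beta, params)
            res = rms_difference(border, traj, bin_width)
        except (DegenerateTrajectoryError, NoOverlapError):
            continue
        if best is None or res.rms < best[1].rms:
            best = (phi0, res)
    if best is None:
        raise FitFailureError(
            f"no candidate phi0 overlaps the border (beta={beta})"
        )
    phi0, res = best
    phi0_ext = phi0 + 360.0 if border.hemifield == "inferior" else phi0
    return FitResult(
        beta=float(beta),
        phi0_best=float(phi0_ext),
        theta_c_best=clock_hour_from_phi(phi0),
        rms=res.rms,
        n_bins_used=res.n_bins,
        coverage=res.coverage,
    )


def normalize_rms(rms_values) -> np.ndarray:
    """Within-arcuate normalization: z-score -> standard-normal percentile.

    Uses the sample (n-1) standard deviation.  If the values are all
    equal (zero spread) every percentile is 50.  NaNs (failed fits)
    propagate and are excluded from the mean/SD.
    """
    x = np.asarray(rms_values, dtype=float)
    sd = np.nanstd(x, ddof=1)
    if not np.isfinite(sd) or sd == 0.0:
        out = np.full_like(x, 50.0)
        out[np.isnan(x)] = np.nan
        return out
    z = (x - np.nanmean(x)) / sd
    return 100.0 * norm.cdf(z)


def sweep_betas(
    border: ArcuateBorder,
    geometry: ScanGeometry,
    params: BundleModelParams = BundleModelParams(),
    *,
    phi0_step: float = PHI0_STEP_DEFAULT,
    bin_width: float = BIN_WIDTH_DEFAULT,
) -> BetaSweep:
    """Fit all 11 grid beta values to one border and normalize their RMS."""
    betas = beta_grid(border.hemifield)
    results: list[FitResult | None] = []
    rms = np.full(11, np.nan)
    for i, b in enumerate(betas):
        try:
            fit = best_fit_phi0(
                border, float(b), geometry, params,
                phi0_step=phi0_step, bin_width=bin_width,
            )
        except FitFailureError:
            results.append(None)
            continue
        results.append(fit)
        rms[i] = fit.rms
    if all(f is None for f in results):
        raise FitFailureError("all 11 beta values failed to fit the border")
    return BetaSweep(
        region=border.hemifield,
        betas=betas,
        results=results,
        normalized=normalize_rms(rms),
        side=border.side,
    )


def cohort_percentile_summary(
    sweeps: Sequence[BetaSweep], region: str | None = None
) -> pd.DataFrame:
    """Per-beta 2.5th / 50th / 97.5th percentiles of normalized RMS values
    across arcuates (linear-interpolation quantiles).

    Returns a DataFrame indexed by beta with columns p2.5, p50, p97.5.
    """
    if region is not None:
        sweeps = [s for s in sweeps if s.region == region]
    if not sweeps:
        raise ValueError("no sweeps to summarize")
    regions = {s.region for s in sweeps}
    if len(regions) > 1:
        raise ValueError("cannot pool superior and inferior sweeps")
    betas = sweeps[0].betas
    mat = np.vstack([s.normalized for s in sweeps])  # (n_arcuates, 11)
    q = np.nanpercentile(mat, [2.5, 50.0, 97.5], axis=0)
    return pd.DataFrame(
        {"p2.5": q[0], "p50": q[1], "p97.5": q[2]},
        index=pd.Index(betas, name="beta"),
    )


def fit_pmap(
    pmap: PMap,
    seed: PointDeg | None = None,
    params: BundleModelParams = BundleModelParams(),
    *,
    phi0_step: float = PHI0_STEP_DEFAULT,
    bin_width: float = BIN_WIDTH_DEFAULT,
    min_angular_extent: float = 20.0,
    roi: np.ndarray | None = None,
) -> list[BetaSweep]:
    """Full pipeline on one probability map: binarize, select the arcuate
    component(s), extract and split borders, sweep the beta grid.

    OS maps are mirrored into the right-eye frame first.  Without a seed
    point, each hemifield containing a qualifying component contributes
    one arcuate (two sweeps: upper and lower border); with a seed, only
    the seeded component is processed.

    Raises :class:`NoArcuateError` when no hemifield holds an arcuate.
    """
    if pmap.geometry.laterality == "OS":
        pmap = mirror_pmap(pmap)
        if seed is not None:
            seed = PointDeg(-seed.x, seed.y)
    mask = binarize_pmap(pmap)
    if roi is not None:
        from .borders import BinaryMask

        mask = BinaryMask(mask.grid & np.asarray(roi, dtype=np.uint8), pmap)
    components = []
    if seed is not None:
        components.append(select_arcuate_component(mask, seed))
    else:
        for hemi in ("superior", "inferior"):
            try:
                components.append(
                    select_arcuate_component(
                        mask,
                        min_angular_extent=min_angular_extent,
                        hemifield=hemi,
                    )
                )
            except NoArcuateError:
                continue
        if not components:
            raise NoArcuateError("no arcuate-shaped component in either hemifield")
    sweeps: list[BetaSweep] = []
    for comp_id, comp in enumerate(components):
        per = extract_perimeter(comp)
        upper, lower = split_borders(
            per, bin_width=bin_width, component_id=comp_id
        )
        for border in (upper, lower):
            sweeps.append(
                sweep_betas(
                    border, pmap.geometry, params,
                    phi0_step=phi0_step, bin_width=bin_width,
                )
            )
    return sweeps
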