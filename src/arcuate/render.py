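"""Static rendering of the arcuate report.

Two panels: the probability map with the best-fit bounding trajectories
(plus intermediate fill trajectories between the bounds) overlaid, and
the cpRNFL TSNIT plot with normative 5% / 1% bands and the
trajectory-determined bounds marked.  Rendering is deterministic: fixed
figure geometry, fixed colors, and empty PNG metadata so identical
inputs produce byte-identical files.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless, deterministic
import matplotlib.pyplot as plt
import numpy as np
from scipy.stats import norm as _norm

from .borders import CAT_OUTSIDE, CAT_P1, CAT_P5, PMap
from .cprnfl import CpRNFLProfile
from .fitting import BetaSweep
from .geometry import tsnit_from_phi, wrap_phi
from .model import BundleModelParams, sample_trajectory

__all__ = ["render_report"]

_CAT_COLORS = {
    0: (1.0, 1.0, 1.0),  # normal
    CAT_P5: (1.0, 0.85, 0.2),  # <=5%
    CAT_P1: (0.9, 0.15, 0.15),  # <=1%
    CAT_OUTSIDE: (0.75, 0.75, 0.75),
}


def _pmap_rgb(pmap: PMap) -> np.ndarray:
    rgb = np.ones(pmap.grid.shape + (3,))
    for code, color in _CAT_COLORS.items():
        rgb[pmap.grid == code] = color
    return rgb


def _overlay_trajectories(ax, pmap: PMap, sweeps, params, fill_step=5.0):
    """Draw best-fit bound trajectories (at each sweep's best beta) and
    intermediate fill trajectories between the two bounds."""
    geom = pmap.geometry
    bounds = []
    for sweep in sweeps:
        fit = sweep.results[int(np.nanargmin(sweep.normalized))]
        if fit is None:
            continue
        bounds.append((wrap_phi(fit.phi0_best), fit.beta))
    for phi0, beta in bounds:
        traj = sample_trajectory(geom, phi0, beta, params)
        ax.plot(traj.polyline[:, 0], traj.polyline[:, 1], color="k", lw=1.5)
    if len(bounds) == 2:
        (p_a, b_a), (p_b, _) = bounds
        lo, hi = sorted((p_a, p_b))
        for phi0 in np.arange(lo + fill_step, hi, fill_step):
            traj = sample_trajectory(geom, float(phi0), b_a, params)
            ax.plot(
                traj.polyline[:, 0], traj.polyline[:, 1],
                color="0.35", lw=0.6,
            )


def render_report(
    pmap: PMap,
    sweeps: list[BetaSweep],
    profile: CpRNFLProfile | None,
    out_path: str | Path,
    params: BundleModelParams = BundleModelParams(),
) -> Path:
    """Render the arcuate report to a PNG file and return its path.

    Missing pieces degrade gracefully: with no sweeps only the raw map is
    shown (with a warning); with no profile the TSNIT panel is omitted.
    """
    out_path = Path(out_path)
    if not sweeps:
        warnings.warn("no fit results: rendering the probability map only")

    ncols = 2 if profile is not None else 1
    fig, axes = plt.subplots(
        1, ncols, figsize=(6.0 * ncols, 5.0), squeeze=False, dpi=100
    )
    ax = axes[0, 0]
    nrow, ncol = pmap.grid.shape
    x0, y0 = pmap.origin
    extent = [
        x0 - pmap.pixel_size / 2,
        x0 + (ncol - 0.5) * pmap.pixel_size,
        y0 - (nrow - 0.5) * pmap.pixel_size,
        y0 + pmap.pixel_size / 2,
    ]
    ax.imshow(_pmap_rgb(pmap), extent=extent, origin="upper", aspect="equal")
    _overlay_trajectories(ax, pmap, sweeps, params)
    circle = plt.Circle(
        pmap.geometry.bmo_center, pmap.geometry.r_c_deg,
        fill=False, color="b", lw=1.0,
    )
    ax.add_patch(circle)
    ax.set_xlabel("x (deg, nasal +)")
    ax.set_ylabel("y (deg, superior +)")
    ax.set_title("RNFL p-map with fitted trajectories")

    if profile is not None:
        axp = axes[0, 1]
        t = profile.positions
        t5 = profile.norm_mean + _norm.ppf(0.05) * profile.norm_sd
        t1 = profile.norm_mean + _norm.ppf(0.01) * profile.norm_sd
        axp.fill_between(t, 0, t1, color=_CAT_COLORS[CAT_P1], alpha=0.6)
        axp.fill_between(t, t1, t5, color=_CAT_COLORS[CAT_P5], alpha=0.6)
        axp.plot(t, profile.norm_mean, color="0.4", lw=0.8, label="norm mean")
        axp.plot(t, profile.thickness, color="k", lw=1.4, label="thickness")
        for sweep in sweeps:
            fit = sweep.results[int(np.nanargmin(sweep.normalized))]
            if fit is None:
                continue
            axp.axvline(
                tsnit_from_phi(wrap_phi(fit.phi0_best)),
                color="b", lw=1.0, ls="--",
            )
        axp.set_xlim(0, 360)
        axp.set_ylim(bottom=0)
        axp.set_xticks([0, 90, 180, 270, 360])
        axp.set_xticklabels(["T", "S", "N", "I", "T"])
        axp.set_xlabel("TSNIT position")
        axp.set_ylabel("cpRNFL thickness (µm)")
        axp.set_title("cpRNFL profile with fitted bounds")
        axp.legend(loc="upper right", fontsize=8)

    fig.tight_layout()
    fig.savefig(out_path, metadata={"Software": None})
    plt.close(fig)
    return out_path
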