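"""File formats: probability-map rasters, borders, profiles and fit tables.

PMaps travel as an 8-bit single-channel PNG (or an integer CSV) of
category codes {0 normal, 1 p<=5, 2 p<=1, 255 outside-field} plus a JSON
sidecar holding the georeferencing (pixel size, origin) and the scan
geometry.  Borders and cpRNFL profiles are plain CSV; fit results are
JSON (nested) and CSV (one row per border x beta).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .borders import ArcuateBorder, PMap
from .cprnfl import CpRNFLProfile
from .fitting import BetaSweep
from .geometry import PointDeg, ScanGeometry

__all__ = [
    "save_pmap",
    "load_pmap",
    "save_borders",
    "load_borders",
    "save_profile",
    "load_profile",
    "sweeps_to_json",
    "sweeps_to_frame",
]


def _sidecar_path(raster_path: Path) -> Path:
    return raster_path.with_suffix(".json")


def save_pmap(pmap: PMap, path: str | Path) -> None:
    """Write the raster (PNG or CSV by extension) and its JSON sidecar."""
    path = Path(path)
    grid = np.asarray(pmap.grid, dtype=np.uint8)
    if path.suffix.lower() == ".png":
        Image.fromarray(grid, mode="L").save(path)
    elif path.suffix.lower() == ".csv":
        np.savetxt(path, grid, fmt="%d", delimiter=",")
    else:
        raise ValueError(f"unsupported raster format {path.suffix!r}")
    sidecar = {
        "pixel_size_deg": pmap.pixel_size,
        "origin_xy_deg": [pmap.origin.x, pmap.origin.y],
        **pmap.geometry.to_dict(),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def load_pmap(path: str | Path, sidecar: str | Path | None = None) -> PMap:
    """Read a raster + sidecar pair written by :func:`save_pmap`."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        grid = np.asarray(Image.open(path), dtype=np.uint8)
    elif path.suffix.lower() == ".csv":
        grid = np.loadtxt(path, dtype=np.uint8, delimiter=",")
    else:
        raise ValueError(f"unsupported raster format {path.suffix!r}")
    sidecar = Path(sidecar) if sidecar else _sidecar_path(path)
    meta = json.loads(sidecar.read_text())
    missing = [
        k
        for k in (
            "pixel_size_deg",
            "origin_xy_deg",
            "fovea_xy_deg",
            "bmo_center_xy_deg",
            "fd_angle_deg",
            "r_c_deg",
            "laterality",
        )
        if k not in meta
    ]
    if missing:
        raise ValueError(f"pmap sidecar is missing keys: {missing}")
    return PMap(
        grid=grid,
        pixel_size=float(meta["pixel_size_deg"]),
        origin=PointDeg(*meta["origin_xy_deg"]),
        geometry=ScanGeometry.from_dict(meta),
    )


def save_borders(borders: list[ArcuateBorder], path: str | Path) -> None:
    """Borders as CSV with columns r_deg, phi_deg, side, hemifield."""
    frames = [
        pd.DataFrame(
            {
                "r_deg": b.r,
                "phi_deg": b.phi,
                "side": b.side,
                "hemifield": b.hemifield,
            }
        )
        for b in borders
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_borders(path: str | Path) -> list[ArcuateBorder]:
    df = pd.read_csv(path)
    out = []
    for (side, hemi), g in df.groupby(["side", "hemifield"], sort=False):
        out.append(
            ArcuateBorder(
                g["r_deg"].to_numpy(),
                g["phi_deg"].to_numpy(),
                str(side),
                str(hemi),
            )
        )
    return out


def save_profile(profile: CpRNFLProfile, path: str | Path) -> None:
    pd.DataFrame(
        {
            "tsnit_deg": profile.positions,
            "thickness_um": profile.thickness,
            "norm_mean_um": profile.norm_mean,
            "norm_sd_um": profile.norm_sd,
        }
    ).to_csv(path, index=False)


def load_profile(path: str | Path) -> CpRNFLProfile:
    df = pd.read_csv(path)
    return CpRNFLProfile(
        df["tsnit_deg"].to_numpy(),
        df["thickness_um"].to_numpy(),
        df["norm_mean_um"].to_numpy(),
        df["norm_sd_um"].to_numpy(),
    )


def sweeps_to_frame(sweeps: list[BetaSweep]) -> pd.DataFrame:
    """One row per (border, beta) across all sweeps."""
    return pd.concat([s.to_frame() for s in sweeps], ignore_index=True)


def sweeps_to_json(sweeps: list[BetaSweep]) -> dict:
    """Nested JSON-serializable structure of all sweeps."""
    return {
        "sweeps": [
            {
                "region": s.region,
                "side": s.side,
                "betas": [float(b) for b in s.betas],
                "normalized_pct": [float(v) for v in s.normalized],
                "best_beta": s.best_beta,
                "fits": [
                    (r.to_dict() if r is not None else None) for r in s.results
                ],
            }
            for s in sweeps
        ]
    }
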