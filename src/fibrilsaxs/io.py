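"""File formats and the azimuthal-regrouping utility.

Profiles travel as plain columnar text (header ``# q_nm^-1 I sigma``); a
scan is a directory with an ``index.csv`` (row, col, x_um, y_um, path,
truth_json) and one profile file per pixel.  2D detector frames are
accepted only as plain arrays with beam-center / pixel-pitch geometry and
regrouped into per-segment 1D profiles.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .profiles import QProfile, ScanGrid

__all__ = [
    "read_profile",
    "write_profile",
    "write_scan",
    "read_scan",
    "fold_azimuthal",
]

_HEADER = "# q_nm^-1 I sigma"


def write_profile(profile: QProfile, path) -> None:
    """Write a profile as columnar text (2 or 3 columns)."""
    path = Path(path)
    cols = [profile.q, profile.intensity]
    if profile.sigma is not None:
        cols.append(profile.sigma)
    header = _HEADER if profile.sigma is not None else _HEADER.rsplit(" ", 1)[0]
    with path.open("w") as fh:
        fh.write(header + "\n")
        fh.write(f"# modality {profile.modality}\n")
        for row in zip(*cols):
            # repr precision => lossless float round trip
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_profile(path, modality: Optional[str] = None) -> QProfile:
    """Read a columnar-text profile; validates q monotonicity per line.

    A 3rd column, when present, is the per-point uncertainty.
    """
    path = Path(path)
    q, i, s = [], [], []
    ncols = None
    file_modality = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) == 2 and parts[0] == "modality":
                    file_modality = parts[1]
                continue
            parts = line.split()
            if ncols is None:
                if len(parts) not in (2, 3):
                    raise ValueError(f"{path}:{lineno}: expected 2 or 3 columns")
                ncols = len(parts)
            elif len(parts) != ncols:
                raise ValueError(f"{path}:{lineno}: inconsistent column count")
            try:
                vals = [float(v) for v in parts]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value") from exc
            if any(math.isnan(v) for v in vals):
                raise ValueError(f"{path}:{lineno}: NaN value")
            if q and vals[0] <= q[-1]:
                raise ValueError(f"{path}:{lineno}: q not strictly increasing")
            q.append(vals[0])
            i.append(vals[1])
            if ncols == 3:
                s.append(vals[2])
    if not q:
        raise ValueError(f"{path}: empty profile")
    return QProfile(
        np.array(q), np.array(i),
        np.array(s) if s else None,
        modality or file_modality or "saxs",
    )


def write_scan(grid: ScanGrid, out_dir) -> None:
    """Write a scan as a directory: index.csv plus per-pixel profile files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for row, col, p in grid.pixels():
        name = f"px_{row:03d}_{col:03d}.dat"
        write_profile(p, out_dir / name)
        x, y = grid.position_um(row, col)
        records.append({
            "row": row, "col": col, "x_um": x, "y_um": y, "path": name,
            "truth_json": json.dumps(p.meta.get("truth", {})),
        })
    pd.DataFrame.from_records(records).to_csv(out_dir / "index.csv", index=False)
    meta = {"n_rows": grid.n_rows, "n_cols": grid.n_cols,
            "step_um": grid.step_um, **{k: v for k, v in grid.meta.items()
                                        if isinstance(v, (int, float, str))}}
    (out_dir / "scan.json").write_text(json.dumps(meta, indent=1))


def read_scan(in_dir) -> ScanGrid:
    """Read a scan directory written by :func:`write_scan`."""
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "scan.json").read_text())
    index = pd.read_csv(in_dir / "index.csv")
    n_rows, n_cols = int(meta["n_rows"]), int(meta["n_cols"])
    profiles: list[list[Optional[QProfile]]] = [
        [None] * n_cols for _ in range(n_rows)
    ]
    modality = meta.get("modality")
    for rec in index.itertuples():
        p = read_profile(in_dir / rec.path, modality=modality)
        truth = json.loads(rec.truth_json) if isinstance(rec.truth_json, str) else {}
        if truth:
            p.meta["truth"] = truth
        p.meta["row"], p.meta["col"] = int(rec.row), int(rec.col)
        profiles[int(rec.row)][int(rec.col)] = p
    if any(p is None for row in profiles for p in row):
        raise ValueError(f"{in_dir}: index.csv does not cover the full grid")
    return ScanGrid(n_rows, n_cols, float(meta["step_um"]), profiles,
                    {k: v for k, v in meta.items()
                     if k not in ("n_rows", "n_cols", "step_um")})


def fold_azimuthal(
    frame: np.ndarray,
    beam_center: tuple[float, float],
    pixel_pitch_mm: float,
    distance_mm: float,
    wavelength_nm: float,
    n_segments: int = 16,
    n_qbins: int = 200,
) -> list[QProfile]:
    """Regroup a 2D frame into per-segment azimuthally averaged 1D profiles.

    ``beam_center`` is (row, col) in pixels.  Segment 0 starts at the
    +horizontal axis and segments proceed counter-clockwise.  The scattering
    vector is q = 4 pi sin(theta) / lambda with 2 theta the scattering angle
    from the pixel radius.  The full-azimuth average equals the
    pixel-count-weighted mean over segments.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be a 2D array")
    cy, cx = beam_center
    if not (0 <= cy < frame.shape[0] and 0 <= cx < frame.shape[1]):
        raise ValueError("beam center outside the frame")
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    yy, xx = np.indices(frame.shape)
    dx, dy = xx - cx, yy - cy
    r_mm = np.hypot(dx, dy) * pixel_pitch_mm
    two_theta = np.arctan2(r_mm, distance_mm)
    q = 4.0 * np.pi * np.sin(two_theta / 2.0) / wavelength_nm
    # counter-clockwise azimuth from +horizontal; image rows grow downward
    azi = np.arctan2(-dy, dx) % (2.0 * np.pi)
    seg = np.minimum((azi / (2.0 * np.pi) * n_segments).astype(int),
                     n_segments - 1)

    valid = q > 0
    q_edges = np.linspace(q[valid].min(), q[valid].max(), n_qbins + 1)
    q_centers = 0.5 * (q_edges[:-1] + q_edges[1:])
    profiles = []
    for s in range(n_segments):
        m = valid & (seg == s)
        counts, _ = np.histogram(q[m], bins=q_edges)
        sums, _ = np.histogram(q[m], bins=q_edges, weights=frame[m])
        with np.errstate(invalid="ignore"):
            mean = sums / counts
        keep = counts > 0
        profiles.append(QProfile(q_centers[keep], mean[keep], None, "saxs",
                                 {"segment": s, "pixel_counts": counts[keep]}))
    return profiles
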