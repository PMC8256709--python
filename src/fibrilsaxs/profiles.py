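"""Core in-memory containers: 1D scattering profiles and raster-scan grids.

Conventions
-----------
* The scattering-vector magnitude ``q`` is in nm^-1 everywhere.
* Real-space length scales are reported as ``d = 2*pi/q`` (inter-planar /
  inter-fibril convention), never ``1/q``.
* Intensities are detector counts (arbitrary units); an optional per-point
  uncertainty accompanies them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator, Optional

import numpy as np

__all__ = ["QProfile", "ScanGrid"]


@dataclass
class QProfile:
    """One azimuthally averaged 1D scattering curve.

    Parameters
    ----------
    q : array of float
        Scattering-vector magnitudes in nm^-1, strictly increasing, > 0.
    intensity : array of float
        Scattered intensity in counts (arbitrary units), same length as ``q``.
    sigma : array of float, optional
        One-standard-deviation uncertainty per point.
    modality : {"saxs", "waxs"}
        Which angular regime the curve covers.
    meta : dict
        Free-form metadata (e.g. the ground truth of a synthetic profile).
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: Optional[np.ndarray] = None
    modality: str = "saxs"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.q.size == 0:
            raise ValueError("q must be a non-empty 1D array")
        if self.intensity.shape != self.q.shape:
            raise ValueError("intensity must have the same shape as q")
        if np.any(self.q <= 0):
            raise ValueError("q must be strictly positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma must have the same shape as q")
        if self.modality not in ("saxs", "waxs"):
            raise ValueError(f"unknown modality {self.modality!r}")

    def __len__(self) -> int:
        return self.q.size

    def crop(self, q_min: float, q_max: float) -> "QProfile":
        """Return the sub-profile with q_min <= q <= q_max."""
        mask = (self.q >= q_min) & (self.q <= q_max)
        if not np.any(mask):
            raise ValueError(f"no data in q range [{q_min}, {q_max}]")
        return QProfile(
            self.q[mask],
            self.intensity[mask],
            None if self.sigma is None else self.sigma[mask],
            self.modality,
            dict(self.meta),
        )

    def interpolated(self, q_new: np.ndarray) -> "QProfile":
        """Resample onto a new q grid by linear interpolation."""
        q_new = np.asarray(q_new, dtype=float)
        i_new = np.interp(q_new, self.q, self.intensity)
        s_new = None
        if self.sigma is not None:
            s_new = np.interp(q_new, self.q, self.sigma)
        return QProfile(q_new, i_new, s_new, self.modality, dict(self.meta))


@dataclass
class ScanGrid:
    """A raster scan of 1D profiles — the unit of one sample.

    Profiles are indexed ``grid[row, col]``; position metadata follows the
    beamline convention of a regular raster with a fixed step in micrometres.
    """

    n_rows: int
    n_cols: int
    step_um: float
    profiles: list[list[QProfile]]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if len(self.profiles) != self.n_rows or any(
            len(r) != self.n_cols for r in self.profiles
        ):
            raise ValueError("profiles must be an n_rows x n_cols nested list")

    def __getitem__(self, rc: tuple[int, int]) -> QProfile:
        row, col = rc
        return self.profiles[row][col]

    def __len__(self) -> int:
        return self.n_rows * self.n_cols

    def pixels(self) -> Iterator[tuple[int, int, QProfile]]:
        """Iterate (row, col, profile) in raster order."""
        for row in range(self.n_rows):
            for col in range(self.n_cols):
                yield row, col, self.profiles[row][col]

    def position_um(self, row: int, col: int) -> tuple[float, float]:
        """(x, y) stage position of a pixel in micrometres."""
        return col * self.step_um, row * self.step_um

    def average_profile(self) -> QProfile:
        """Mean intensity over all pixels (common q grid assumed).

        This is the per-sample average curve on which the step-model fit and
        the asymmetry statistic operate.
        """
        q0 = self.profiles[0][0].q
        acc = np.zeros_like(q0)
        for _, _, p in self.pixels():
            if p.q.shape != q0.shape or not np.allclose(p.q, q0):
                acc += np.interp(q0, p.q, p.intensity)
            else:
                acc += p.intensity
        acc /= len(self)
        return QProfile(q0, acc, None, self.profiles[0][0].modality, {"averaged": len(self)})

    def intensity_matrix(self) -> np.ndarray:
        """All profiles stacked as an (n_pixels, n_q) matrix in raster order."""
        return np.stack([p.intensity for _, _, p in self.pixels()])
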