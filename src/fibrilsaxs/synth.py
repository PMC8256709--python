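"""Synthetic SAXS/WAXS profiles and scan grids with recorded ground truth.

No public data accompany the scanning-microscopy experiment this package
analyses, so every downstream stage is exercised on synthetic scans that
emulate its statistical structure:

* meridional SAXS curves from the periodic two-level electron-density model
  (:mod:`fibrilsaxs.stepmodel`) with Poisson counting noise,
* WAXS curves as Gaussian peaks near q ~ 4 nm^-1 (lateral triple-helix
  spacing, ~1.5 nm) and q ~ 22 nm^-1 (axial amino-acid rise, ~0.286 nm) on a
  power-law background,
* raster grids with smoothly varying parameters plus optional rectangular
  outlier regions carrying an alternative ground truth.

Determinism: one master seed; the stream for pixel (row, col) is derived
from ``(seed, row, col)`` so any pixel can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .profiles import QProfile, ScanGrid
from .stepmodel import StepDensityParams, forward_intensity

__all__ = [
    "GroundTruth",
    "OutlierRegion",
    "SyntheticScanSpec",
    "default_saxs_q_grid",
    "default_waxs_q_grid",
    "generate_saxs_profile",
    "generate_waxs_profile",
    "generate_scan",
]


def default_saxs_q_grid(n: int = 1000) -> np.ndarray:
    """0.05-1.2 nm^-1: brackets Bragg orders 1-12 of a ~65 nm period."""
    return np.linspace(0.05, 1.2, n)


def default_waxs_q_grid(n: int = 1500) -> np.ndarray:
    """2-28 nm^-1: brackets the ~4 and ~22 nm^-1 collagen WAXS peaks."""
    return np.linspace(2.0, 28.0, n)


@dataclass
class GroundTruth:
    """Complete description of one synthetic pixel.

    Attributes
    ----------
    step_params : StepDensityParams
        Axial step-density model parameters governing the SAXS curve.
    waxs_peaks : list of (q0, amplitude, fwhm)
        Gaussian WAXS peaks; positions/widths in nm^-1, amplitude in counts.
    background : (A, n, floor)
        Power-law background A * q^-n plus a constant floor, in counts
        (applied to WAXS; the SAXS background is the model's own monotone
        term, plus the floor).
    count_scale : float
        Expected counts at the third-order meridional Bragg peak; sets the
        Poisson noise level.
    seed : int
        Per-truth random seed (combined with pixel indices in scans).
    """

    step_params: StepDensityParams
    waxs_peaks: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(4.0, 400.0, 0.8), (22.0, 250.0, 1.2)]
    )
    background: tuple[float, float, float] = (2000.0, 1.5, 5.0)
    count_scale: float = 1.0e4
    seed: int = 0

    def __post_init__(self) -> None:
        for q0, amp, fwhm in self.waxs_peaks:
            if q0 <= 0:
                raise ValueError("WAXS peak position q0 must be positive")
            if amp < 0:
                raise ValueError("WAXS peak amplitude must be non-negative")
            if fwhm <= 0:
                raise ValueError("WAXS peak fwhm must be positive")
        if self.count_scale <= 0:
            raise ValueError("count_scale must be positive")

    def replace(self, **kw) -> "GroundTruth":
        d = {
            "step_params": self.step_params,
            "waxs_peaks": list(self.waxs_peaks),
            "background": self.background,
            "count_scale": self.count_scale,
            "seed": self.seed,
        }
        d.update(kw)
        return GroundTruth(**d)

    def to_dict(self) -> dict:
        return {
            "step_params": self.step_params.to_dict(),
            "waxs_peaks": [list(p) for p in self.waxs_peaks],
            "background": list(self.background),
            "count_scale": self.count_scale,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            step_params=StepDensityParams(**d["step_params"]),
            waxs_peaks=[tuple(p) for p in d["waxs_peaks"]],
            background=tuple(d["background"]),
            count_scale=d["count_scale"],
            seed=d["seed"],
        )


def default_truth(seed: int = 0) -> GroundTruth:
    """The canonical hydrated-collagen ground truth used across the tests.

    D = 65.5 nm, sigma = 0.46, delta_rho = 0.08, N = 10, mild damping
    (w = 9 nm, c = 0.05) — the regime of a non-glycated control sample.
    """
    return GroundTruth(
        step_params=StepDensityParams(
            D=65.5, N=10, sigma=0.46, rho_ave=1.0, delta_rho=0.08, w=9.0, c=0.05
        ),
        seed=seed,
    )


@dataclass
class OutlierRegion:
    """Rectangle [row0, row1) x [col0, col1) carrying an alternative truth."""

    row0: int
    row1: int
    col0: int
    col1: int
    truth: GroundTruth

    def contains(self, row: int, col: int) -> bool:
        return self.row0 <= row < self.row1 and self.col0 <= col < self.col1


@dataclass
class SyntheticScanSpec:
    """Recipe for a synthetic raster scan.

    ``parameter_maps`` holds optional per-pixel overrides of step-model
    parameters: each entry maps a parameter name (e.g. ``"D"``) to either a
    scalar or an (n_rows, n_cols) array evaluated per pixel.  Smooth maps
    emulate the lateral homogeneity of the real samples; abrupt structure
    is injected only through ``outlier_regions``.
    """

    base_truth: GroundTruth
    n_rows: int = 81
    n_cols: int = 51
    step_um: float = 50.0
    modality: str = "saxs"
    parameter_maps: dict[str, object] = field(default_factory=dict)
    outlier_regions: list[OutlierRegion] = field(default_factory=list)
    noise_model: str = "poisson"
    q_grid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.noise_model not in ("poisson", "none"):
            raise ValueError("noise_model must be 'poisson' or 'none'")
        if self.modality not in ("saxs", "waxs"):
            raise ValueError("modality must be 'saxs' or 'waxs'")
        for reg in self.outlier_regions:
            if not (0 <= reg.row0 < reg.row1 <= self.n_rows
                    and 0 <= reg.col0 < reg.col1 <= self.n_cols):
                raise ValueError(
                    f"outlier rectangle ({reg.row0},{reg.row1},{reg.col0},"
                    f"{reg.col1}) outside the {self.n_rows}x{self.n_cols} grid"
                )

    def truth_at(self, row: int, col: int) -> GroundTruth:
        """Resolve the ground truth of one pixel (outliers take precedence)."""
        for reg in self.outlier_regions:
            if reg.contains(row, col):
                return reg.truth
        if not self.parameter_maps:
            return self.base_truth
        kw = {}
        for name, m in self.parameter_maps.items():
            v = m[row, col] if isinstance(m, np.ndarray) else m
            kw[name] = float(v)
        return self.base_truth.replace(
            step_params=self.base_truth.step_params.replace(**kw)
        )


def _pixel_rng(seed: int, row: int, col: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(row), int(col)])


def _noiseless_saxs(truth: GroundTruth, q_grid: np.ndarray) -> np.ndarray:
    model = forward_intensity(q_grid, truth.step_params)
    # calibrate so the expected counts at the 3rd-order Bragg peak equal
    # count_scale; the floor adds a detector/dark level
    q3 = truth.step_params.bragg_q(3)
    ref = forward_intensity(np.array([q3]), truth.step_params)[0]
    floor = truth.background[2]
    return truth.count_scale / ref * model + floor


def generate_saxs_profile(
    truth: GroundTruth,
    q_grid: Optional[np.ndarray] = None,
    noise: str = "poisson",
    rng: Optional[np.random.Generator] = None,
) -> QProfile:
    """Meridional SAXS curve from the step-density model of ``truth``.

    With ``noise="poisson"`` the expected counts are Poisson sampled (seeded
    from ``truth.seed`` unless ``rng`` is supplied) and a sqrt(counts)
    uncertainty column is attached.  The ground truth travels in
    ``profile.meta["truth"]``.
    """
    if q_grid is None:
        q_grid = default_saxs_q_grid()
    q_grid = np.asarray(q_grid, dtype=float)
    if np.any(q_grid <= 0):
        raise ValueError("q_grid must be strictly positive")
    expected = _noiseless_saxs(truth, q_grid)
    if noise == "poisson":
        if rng is None:
            rng = np.random.default_rng(truth.seed)
        intensity = rng.poisson(expected).astype(float)
        sigma = np.sqrt(np.maximum(intensity, 1.0))
    elif noise == "none":
        intensity, sigma = expected, None
    else:
        raise ValueError("noise must be 'poisson' or 'none'")
    return QProfile(q_grid, intensity, sigma, "saxs", {"truth": truth.to_dict()})


def _noiseless_waxs(truth: GroundTruth, q_grid: np.ndarray) -> np.ndarray:
    A, n, floor = truth.background
    y = A * q_grid ** (-n) + floor
    for q0, amp, fwhm in truth.waxs_peaks:
        s = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        y = y + amp * np.exp(-0.5 * ((q_grid - q0) / s) ** 2)
    return y


def generate_waxs_profile(
    truth: GroundTruth,
    q_grid: Optional[np.ndarray] = None,
    noise: str = "poisson",
    rng: Optional[np.random.Generator] = None,
) -> QProfile:
    """WAXS curve: Gaussian peaks on an A*q^-n + floor background."""
    if q_grid is None:
        q_grid = default_waxs_q_grid()
    q_grid = np.asarray(q_grid, dtype=float)
    if np.any(q_grid <= 0):
        raise ValueError("q_grid must be strictly positive")
    expected = _noiseless_waxs(truth, q_grid)
    if noise == "poisson":
        if rng is None:
            rng = np.random.default_rng(truth.seed)
        intensity = rng.poisson(expected).astype(float)
        sigma = np.sqrt(np.maximum(intensity, 1.0))
    elif noise == "none":
        intensity, sigma = expected, None
    else:
        raise ValueError("noise must be 'poisson' or 'none'")
    return QProfile(q_grid, intensity, sigma, "waxs", {"truth": truth.to_dict()})


def generate_scan(spec: SyntheticScanSpec, seed: Optional[int] = None) -> ScanGrid:
    """Generate the full raster scan described by ``spec``.

    Each pixel draws from an independent stream derived from
    ``(seed, row, col)`` so the scan is reproducible pixel-by-pixel; the
    per-pixel ground truth is serialized into each profile's metadata.
    """
    if seed is None:
        seed = spec.base_truth.seed
    q_grid = spec.q_grid
    if q_grid is None:
        q_grid = (default_saxs_q_grid() if spec.modality == "saxs"
                  else default_waxs_q_grid())
    gen = generate_saxs_profile if spec.modality == "saxs" else generate_waxs_profile
    rows = []
    for r in range(spec.n_rows):
        row_profiles = []
        for c in range(spec.n_cols):
            truth = spec.truth_at(r, c)
            rng = _pixel_rng(seed, r, c) if spec.noise_model == "poisson" else None
            p = gen(truth, q_grid, noise=spec.noise_model, rng=rng)
            p.meta["row"], p.meta["col"] = r, c
            row_profiles.append(p)
        rows.append(row_profiles)
    return ScanGrid(spec.n_rows, spec.n_cols, spec.step_um, rows,
                    {"seed": seed, "modality": spec.modality})
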