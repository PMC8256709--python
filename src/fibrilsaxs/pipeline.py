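"""Run configuration and the per-sample analysis orchestrator.

``run_sample`` ties the stages together in the order they are applied to a
real sample: segmentation screen, per-pixel peak maps with histogram
condensation at each length-scale window, step-model fit of the average
meridional profile, Bragg-order asymmetry and the sigma error landscape.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import stepmodel
from .asymmetry import asymmetry_value, index_orders
from .peakfit import DEFAULT_WINDOWS, PeakWindow, scan_peaks, summarize_histogram
from .profiles import ScanGrid
from .segmentation import segment_scan

__all__ = ["RunConfig", "run_sample"]


@dataclass
class RunConfig:
    """All tunables of one analysis run.

    Defaults mirror the staged-fit prescription: sigma starts at 0.46,
    at most 10 outer iterations, contrast step 0.001, damping steps 0.1 nm
    (w) and 0.01 (c), refinement steps 0.1 nm (D) and 0.001 (sigma).
    """

    windows: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            name: (w.q_range[0], w.q_range[1], w.nominal_d)
            for name, w in DEFAULT_WINDOWS.items()
        }
    )
    fit_qrange: Optional[tuple[float, float]] = None
    sigma0: float = 0.46
    max_iterations: int = 10
    delta_rho_step: float = 0.001
    sigma_step: float = 0.001
    d_step: float = 0.1
    w_step: float = 0.1
    c_step: float = 0.01
    asym_max_order: int = 9
    asym_mode: str = "area"
    landscape_sigma: tuple[float, float, int] = (0.30, 0.70, 81)
    segmentation_k: int = 4
    seed: int = 0
    min_histogram_successes: int = 50
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["windows"] = {k: list(v) for k, v in d["windows"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "windows" in d:
            d["windows"] = {k: tuple(v) for k, v in d["windows"].items()}
        for key in ("fit_qrange", "landscape_sigma"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def dump(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def peak_windows(self) -> dict[str, PeakWindow]:
        return {name: PeakWindow(name, (lo, hi), d)
                for name, (lo, hi, d) in self.windows.items()}


def run_sample(
    config: RunConfig,
    scan_saxs: ScanGrid,
    scan_waxs: Optional[ScanGrid] = None,
    out_dir: Optional[str | Path] = None,
) -> dict:
    """Run the full per-sample workflow and return a report dict.

    Stage failures are recorded per stage (``{"error": ...}``) rather than
    aborting the run; when ``out_dir`` is given every intermediate artifact
    (peak maps, landscape, config) is written there.
    """
    report: dict = {"config": config.to_dict(), "stages": {}}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.dump(out / "config.json")

    # 1. segmentation screen
    try:
        seg = segment_scan(scan_saxs, k=config.segmentation_k, seed=config.seed)
        report["stages"]["segmentation"] = {
            "k": seg.k,
            "abundance": seg.abundance.tolist(),
            "explained_variance_ratio": seg.explained_variance_ratio.tolist(),
        }
        if out is not None:
            np.savetxt(out / "labels.csv",
                       np.column_stack([
                           np.repeat(np.arange(scan_saxs.n_rows), scan_saxs.n_cols),
                           np.tile(np.arange(scan_saxs.n_cols), scan_saxs.n_rows),
                           seg.labels.ravel(),
                           seg.scores[:, 0], seg.scores[:, 1], seg.scores[:, 2],
                       ]),
                       header="row,col,label,pc1,pc2,pc3", delimiter=",",
                       comments="", fmt="%.6g")
    except Exception as exc:  # recorded, not fatal
        report["stages"]["segmentation"] = {"error": str(exc)}

    # 2. per-pixel peak maps and histogram condensation.  A window outside
    # the measured q range is not applicable to this scan and is skipped;
    # a map with too few significant peaks is itself a recorded result
    # (the per-pixel failures are data), not a stage failure.
    windows = config.peak_windows()
    report["stages"]["histograms"] = {}
    for name, window in windows.items():
        grid = scan_waxs if name.startswith("waxs") else scan_saxs
        if grid is None:
            report["stages"]["histograms"][name] = {"skipped": "no scan for modality"}
            continue
        lo, hi = window.q_range
        if lo < grid.profiles[0][0].q[0] or hi > grid.profiles[0][0].q[-1]:
            report["stages"]["histograms"][name] = {"skipped": "window outside q support"}
            continue
        try:
            results = scan_peaks(grid, window)
            if out is not None:
                results.to_csv(out / f"peaks_{name}.csv", index=False)
            entry = {
                "n_success": int(results["success"].sum()),
                "n_total": len(results),
            }
            try:
                summary = summarize_histogram(
                    results, min_successes=config.min_histogram_successes,
                    seed=config.seed)
                entry.update({
                    "weighted_position_q": summary.weighted_position,
                    "weighted_position_d": 2.0 * np.pi / summary.weighted_position,
                    "weighted_fwhm_q": summary.weighted_fwhm,
                    "n_components": summary.n_components,
                })
            except ValueError as exc:
                entry["summary_unavailable"] = str(exc)
            report["stages"]["histograms"][name] = entry
        except Exception as exc:
            report["stages"]["histograms"][name] = {"error": str(exc)}

    # 3. step-model fit of the average meridional profile
    avg = scan_saxs.average_profile()
    try:
        fit = stepmodel.fit_profile(avg, fit_range=config.fit_qrange)
        report["stages"]["step_fit"] = fit.to_dict()
    except Exception as exc:
        fit = None
        report["stages"]["step_fit"] = {"error": str(exc)}

    # 4. asymmetry on the average profile
    try:
        table = index_orders(avg, D_init=fit.params.D if fit else None)
        asym = asymmetry_value(table, max_order=config.asym_max_order,
                               mode=config.asym_mode)
        report["stages"]["asymmetry"] = {
            "value": asym.value,
            "D_est": table.D_est,
            "even_orders": asym.even_orders_used,
            "odd_orders": asym.odd_orders_used,
        }
    except Exception as exc:
        report["stages"]["asymmetry"] = {"error": str(exc)}

    # 5. sigma error landscape around the fit
    if fit is not None:
        lo, hi, n = config.landscape_sigma
        sig = np.linspace(lo, hi, int(n))
        rmse = stepmodel.sigma_landscape(avg, fit, sig)
        gap = 1.0 - sig
        report["stages"]["landscape"] = {
            "gap_fraction_min": float(gap[int(np.argmin(rmse))]),
            "rmse_min": float(np.min(rmse)),
        }
        if out is not None:
            np.savetxt(out / "landscape.csv",
                       np.column_stack([gap, rmse]),
                       header="gap_fraction,rmse", delimiter=",",
                       comments="", fmt="%.8g")
    else:
        report["stages"]["landscape"] = {"error": "no step fit available"}

    report["complete"] = all(
        "error" not in stage
        for key, stage in report["stages"].items() if key != "histograms"
    ) and all("error" not in h for h in report["stages"]["histograms"].values())
    if out is not None:
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
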