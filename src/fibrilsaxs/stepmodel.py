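"""Two-level axial electron-density model of the collagen meridional SAXS signal.

The axial structure of a type-1 collagen micro-fibril repeats with period
``D`` (~63-67 nm) and, within one period, consists of an overlap region of
excess electron density ``rho_1 = rho_ave + delta_rho`` extending ``sigma*D``
and a gap region of density ``rho_2 = rho_ave - delta_rho`` extending
``(1 - sigma)*D``.  In the kinematic approximation the meridional intensity
is the squared Fourier transform of this density sampled over ``N``
coherently interfering periods:

    I(q)  ∝  M(q)  +  Damp(q; w, c) * F(q) * S_N(q)

where

* ``S_N(q) = sin^2(N q D / 2) / sin^2(q D / 2)`` is the finite-grating
  interference term (-> N^2 at the Bragg condition ``q = 2 pi n / D``),
* ``F(q) = (delta_rho^2 / q^2) * |2 e^{i q sigma D} - 1 - e^{i q D}|^2 / 4``
  is the single-period fluctuation structure factor, which at the Bragg
  positions reduces to ``(4 delta_rho^2 / q^2) * sin^2(pi n sigma)`` — hence
  the suppression of even orders for sigma near 0.5,
* ``M(q) = rho_ave^2 / (2 q^2)`` is the monotone contribution of the
  period-average density (the mean of its unresolved rapid fringes, on the
  same normalization as F),
* ``Damp(q; w, c) = c + (1 - c) / (1 + (q w / 2 pi)^2)`` is a Lorentzian
  damping with a high-q floor ``c``, absorbing the finite sharpness of the
  real gap/overlap interfaces.

The fitting routine reproduces a staged coordinate descent: contrast first,
then damping, alternating to convergence, then a refinement of period and
overlap fraction on fixed step grids, the whole cycle capped at ten
iterations.  The overall intensity scale is a linear nuisance parameter
solved in closed form at every error evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks, peak_widths, savgol_filter

from .profiles import QProfile

__all__ = [
    "StepDensityParams",
    "StepFitResult",
    "interference_term",
    "monotone_term",
    "fluctuation_term",
    "diffraction_term",
    "damping",
    "forward_intensity",
    "detect_bragg_peaks",
    "assign_orders",
    "estimate_initial_params",
    "fit_profile",
    "sigma_landscape",
]

#: Default parameter-step sizes of the staged fit.
DELTA_RHO_STEP = 0.001
W_STEP = 0.1  # nm
C_STEP = 0.01
D_STEP = 0.1  # nm
SIGMA_STEP = 0.001
MAX_OUTER_ITER = 10


@dataclass
class StepDensityParams:
    """Parameters of the periodic two-level axial electron density.

    Attributes
    ----------
    D : float
        Axial period in nm.
    N : int
        Number of coherently interfering periods (>= 1).
    sigma : float
        Overlap fraction of the period, in (0, 1).
    rho_ave : float
        Period-average excess electron density (arbitrary units; the fit
        pins this to 1 and reports ``delta_rho`` relative to it).
    delta_rho : float
        Half the overlap/gap density contrast, >= 0, same units as rho_ave.
    w : float
        Damping width parameter in nm, >= 0 (0 disables damping).
    c : float
        High-q damping floor in [0, 1] (1 disables damping).
    """

    D: float
    N: int
    sigma: float
    rho_ave: float = 1.0
    delta_rho: float = 0.0
    w: float = 0.0
    c: float = 0.0

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("D must be positive")
        if int(self.N) != self.N or self.N < 1:
            raise ValueError("N must be an integer >= 1")
        self.N = int(self.N)
        if not 0 < self.sigma < 1:
            raise ValueError("sigma must be in (0, 1)")
        if self.delta_rho < 0:
            raise ValueError("delta_rho must be >= 0")
        if self.w < 0:
            raise ValueError("w must be >= 0")
        if not 0 <= self.c <= 1:
            raise ValueError("c must be in [0, 1]")

    @property
    def rho_overlap(self) -> float:
        """Density of the overlap region, rho_ave + delta_rho."""
        return self.rho_ave + self.delta_rho

    @property
    def rho_gap(self) -> float:
        """Density of the gap region, rho_ave - delta_rho."""
        return self.rho_ave - self.delta_rho

    @property
    def gap_fraction(self) -> float:
        """1 - sigma, the gap fraction of the period."""
        return 1.0 - self.sigma

    def bragg_q(self, n: int | np.ndarray) -> float | np.ndarray:
        """Position of the n-th meridional Bragg order, q_n = 2 pi n / D."""
        return 2.0 * np.pi * np.asarray(n) / self.D

    def replace(self, **kw) -> "StepDensityParams":
        d = asdict(self)
        d.update(kw)
        return StepDensityParams(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class StepFitResult:
    """Outcome of a step-model fit to one (average) SAXS profile."""

    params: StepDensityParams
    r_squared: float
    rmse: float
    n_iterations: int
    fit_range: tuple[float, float]
    converged: bool
    scale: float = 1.0
    init_params: Optional[StepDensityParams] = None

    def to_dict(self) -> dict:
        d = {
            "params": self.params.to_dict(),
            "r_squared": self.r_squared,
            "rmse": self.rmse,
            "n_iterations": self.n_iterations,
            "fit_range": list(self.fit_range),
            "converged": self.converged,
            "scale": self.scale,
        }
        if self.init_params is not None:
            d["init_params"] = self.init_params.to_dict()
        return d


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def interference_term(q: np.ndarray, D: float, N: int) -> np.ndarray:
    """Finite-grating interference factor S_N(q) = sin^2(NqD/2)/sin^2(qD/2).

    The removable singularities at the Bragg condition q D = 2 pi n are
    evaluated by the limit, which equals N^2.
    """
    if D <= 0:
        raise ValueError("D must be positive")
    if N < 1:
        raise ValueError("N must be >= 1")
    q = np.asarray(q, dtype=float)
    x = q * D / 2.0
    sin_x = np.sin(x)
    # Near x = n*pi use the limit sin(Nx)/sin(x) -> N*cos(Nx)/cos(x)
    small = np.abs(sin_x) < 1e-9
    ratio = np.empty_like(x)
    ratio[~small] = np.sin(N * x[~small]) / sin_x[~small]
    ratio[small] = N * np.cos(N * x[small]) / np.cos(x[small])
    return ratio**2


def monotone_term(q: np.ndarray, rho_ave: float) -> np.ndarray:
    """Monotone 1/q^2 contribution of the period-average density.

    The average-density part of the single-period transform, multiplied by
    the grating factor, oscillates as 4 rho_ave^2 sin^2(NqD/2)/q^2; its
    mean over those unresolved fringes is 2 rho_ave^2/q^2.  The model
    carries it divided by the same factor 4 as the fluctuation term, i.e.
    rho_ave^2/(2 q^2), so the relative weight of the two terms — and hence
    the fitted delta_rho / rho_ave ratio — stays physical.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q == 0):
        raise ValueError("q = 0 is outside the model domain")
    return rho_ave**2 / (2.0 * q**2)


def fluctuation_term(
    q: np.ndarray, D: float, sigma: float, delta_rho: float
) -> np.ndarray:
    """Single-period fluctuation structure factor of the two-level cell.

    (delta_rho^2 / q^2) * |2 e^{i q sigma D} - 1 - e^{i q D}|^2 / 4; at the
    Bragg positions q_n = 2 pi n / D this reduces to
    (4 delta_rho^2 / q^2) * sin^2(pi n sigma).
    """
    q = np.asarray(q, dtype=float)
    if np.any(q == 0):
        raise ValueError("q = 0 is outside the model domain")
    phase = np.abs(2.0 * np.exp(1j * q * sigma * D) - 1.0 - np.exp(1j * q * D)) ** 2
    return delta_rho**2 / q**2 * phase / 4.0


def diffraction_term(
    q: np.ndarray, D: float, sigma: float, rho_ave: float, delta_rho: float
) -> np.ndarray:
    """Full single-period term: monotone + fluctuation contribution."""
    return monotone_term(q, rho_ave) + fluctuation_term(q, D, sigma, delta_rho)


def damping(q: np.ndarray, w: float, c: float) -> np.ndarray:
    """Lorentzian damping c + (1 - c)/(1 + (q w / 2 pi)^2).

    Equals 1 at q = 0 (and everywhere for w = 0 or c = 1) and approaches the
    floor c at high q.  Monotonically non-increasing in q.
    """
    if w < 0:
        raise ValueError("w must be >= 0")
    if not 0 <= c <= 1:
        raise ValueError("c must be in [0, 1]")
    q = np.asarray(q, dtype=float)
    return c + (1.0 - c) / (1.0 + (q * w / (2.0 * np.pi)) ** 2)


def forward_intensity(q: np.ndarray, params: StepDensityParams) -> np.ndarray:
    """Model meridional intensity (arbitrary overall scale).

    monotone + Damp(q; w, c) * fluctuation * interference; non-negative
    everywhere.
    """
    q = np.asarray(q, dtype=float)
    if q.size == 0:
        raise ValueError("q grid is empty")
    peaks = (
        damping(q, params.w, params.c)
        * fluctuation_term(q, params.D, params.sigma, params.delta_rho)
        * interference_term(q, params.D, params.N)
    )
    return monotone_term(q, params.rho_ave) + peaks


# ---------------------------------------------------------------------------
# initialization helpers
# ---------------------------------------------------------------------------

def detect_bragg_peaks(
    profile: QProfile,
    q_min: float = 0.2,
    q_max: float = 1.0,
    prominence_frac: float = 0.08,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Locate meridional Bragg peaks above the monotone background.

    The intensity is flattened by multiplying with q^2 (removing the
    1/q^2 envelope), lightly Savitzky-Golay smoothed against counting
    noise, and passed to ``scipy.signal.find_peaks``; peaks with a
    prominence below ``prominence_frac`` of the most prominent one are
    discarded.

    Returns
    -------
    q_peaks, heights, fwhm_q : arrays
        Peak positions [nm^-1], flattened heights and FWHM in q of each
        detected peak, sorted by position.
    """
    sub = profile.crop(q_min, q_max)
    flat = sub.intensity * sub.q**2
    if flat.size >= 15:
        win = max(5, 2 * (flat.size // 100) + 1)
        flat = savgol_filter(flat, win, polyorder=2)
    flat = flat - np.median(flat)
    idx, props = find_peaks(flat, prominence=1e-12)
    if idx.size == 0:
        return np.array([]), np.array([]), np.array([])
    prom = props["prominences"]
    keep = prom >= prominence_frac * prom.max()
    idx = idx[keep]
    widths, _, _, _ = peak_widths(flat, idx, rel_height=0.5)
    dq = np.mean(np.diff(sub.q))
    return sub.q[idx], flat[idx], widths * dq


def assign_orders(
    q_pk: np.ndarray,
    heights: np.ndarray,
    slope0: float,
) -> Optional[tuple[float, float, np.ndarray, np.ndarray]]:
    """Assign integer Bragg orders given a trial slope (2 pi / D guess).

    When two detected peaks round to the same order the taller one is kept
    (the weaker is a noise artifact).  The slope is then re-estimated by a
    through-origin regression of q against order.

    Returns (residual, slope, orders, kept_indices) or None if no
    consistent assignment exists.
    """
    orders = np.round(q_pk / slope0).astype(int)
    if np.any(orders < 1):
        return None
    kept: dict[int, int] = {}
    for i, n in enumerate(orders):
        if n not in kept or heights[i] > heights[kept[n]]:
            kept[n] = i
    idx = np.array(sorted(kept.values()))
    if idx.size < 2:
        return None
    o = orders[idx].astype(float)
    qk = q_pk[idx]
    slope = float(np.dot(qk, o) / np.dot(o, o))
    resid = float(np.sum((qk - slope * o) ** 2))
    return resid, slope, orders[idx], idx


def estimate_initial_params(
    profile: QProfile,
    q_min: float = 0.2,
    q_max: float = 1.0,
) -> StepDensityParams:
    """Initial step-model parameters from the data alone.

    * ``D`` from the higher-order Bragg peak positions: the most intense
      detected peak is assumed to be an odd order (3rd or 5th); each
      candidate anchoring defines an order assignment, and a through-origin
      regression of q_n against n picks the assignment with the smaller
      residual, with D = 2 pi / slope.
    * ``N`` from the FWHM of the sharpest peak: the grating peak is locally
      N^2 sinc^2(N (q - q_n) D / 2), whose FWHM is 5.566 / (N D), so
      N = round(5.566 / (D * FWHM)), clamped to [3, 30].
    * ``sigma`` starts at the nominal overlap fraction 0.46, ``rho_ave`` is
      pinned to 1, contrast and damping start switched off.
    """
    q_pk, heights, fwhm = detect_bragg_peaks(profile, q_min, q_max)
    if q_pk.size < 2:
        raise ValueError(
            f"insufficient orders: found {q_pk.size} Bragg peak(s) in "
            f"[{q_min}, {q_max}] nm^-1, need at least 2"
        )
    anchor = q_pk[np.argmax(heights)]
    best = None
    for n0 in (3, 5):
        res = assign_orders(q_pk, heights, anchor / n0)
        if res is not None and (best is None or res[0] < best[0]):
            best = res
    if best is None:
        raise ValueError("could not assign integer orders to detected peaks")
    D = 2.0 * np.pi / best[1]
    sharpest = float(np.min(fwhm[fwhm > 0])) if np.any(fwhm > 0) else np.inf
    if math.isfinite(sharpest):
        # FWHM of the sinc^2-like grating peak: 2 * 2.783 / (N D) in q
        N = int(np.clip(round(5.566 / (D * sharpest)), 3, 30))
    else:
        N = 10
    return StepDensityParams(D=D, N=N, sigma=0.46, rho_ave=1.0, delta_rho=0.0, w=0.0, c=0.0)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _scaled_sse(q: np.ndarray, y: np.ndarray, params: StepDensityParams) -> tuple[float, float]:
    """Sum of squared residuals with the overall scale K solved exactly.

    K = <m, y> / <m, m> minimizes ||y - K m||^2 for the model vector m.
    """
    m = forward_intensity(q, params)
    mm = float(np.dot(m, m))
    if mm == 0.0:
        return float(np.dot(y, y)), 0.0
    K = float(np.dot(m, y)) / mm
    r = y - K * m
    return float(np.dot(r, r)), K


def _line_search(err_fn, value: float, step: float, lo: float, hi: float,
                 e0: float, max_steps: int = 1000) -> tuple[float, float]:
    """Walk ``value`` on a fixed-step grid while the error strictly decreases.

    Tries the +step direction first, then -step; ties keep the smaller
    parameter change (the incumbent), biasing toward the initialization.
    """
    for direction in (+1.0, -1.0):
        moved = False
        v, e = value, e0
        for _ in range(max_steps):
            v_try = v + direction * step
            if not (lo <= v_try <= hi):
                break
            e_try = err_fn(v_try)
            if e_try < e:
                v, e, moved = v_try, e_try, True
            else:
                break
        if moved:
            return v, e
    return value, e0


def fit_profile(
    profile: QProfile,
    init: Optional[StepDensityParams] = None,
    fit_range: Optional[tuple[float, float]] = None,
) -> StepFitResult:
    """Staged coordinate-descent least-squares fit of the step model.

    The procedure alternates (i) contrast steps of 0.001 in ``delta_rho``
    with (ii) damping steps of 0.1 nm in ``w`` and 0.01 in ``c`` until the
    error stops decreasing, then (iv) refines ``D`` (0.1 nm grid) and
    ``sigma`` (0.001 grid); the whole cycle (v) repeats until the error no
    longer changes, capped at ten outer iterations.  Data before the first
    scattering peak are excluded unless an explicit ``fit_range`` is given.
    ``rho_ave`` stays pinned at its initial value (1 by default) and the
    overall intensity scale is solved in closed form.

    Returns a :class:`StepFitResult`; ``converged`` is False when the cap of
    ten iterations was reached while the error was still moving.
    """
    if init is None:
        init = estimate_initial_params(profile)
    if fit_range is None:
        # exclude data before the first scattering peak
        q_pk, _, fwhm = detect_bragg_peaks(profile)
        if q_pk.size == 0:
            raise ValueError("insufficient orders: no Bragg peaks detected")
        q_lo = max(profile.q[0], q_pk[0] - max(fwhm[0], 0.0))
        fit_range = (float(q_lo), float(profile.q[-1]))
    sub = profile.crop(*fit_range)
    q, y = sub.q, sub.intensity

    p = init.replace()
    sse, _ = _scaled_sse(q, y, p)

    def err_for(name):
        cast = int if name == "N" else float
        def f(v):
            return _scaled_sse(q, y, p.replace(**{name: cast(v)}))[0]
        return f

    n_iter = 0
    converged = False
    for n_iter in range(1, MAX_OUTER_ITER + 1):
        sse_outer_start = sse
        # (i)+(ii)+(iii): alternate contrast and damping until stable
        for _ in range(50):
            sse_inner = sse
            v, sse = _line_search(err_for("delta_rho"), p.delta_rho,
                                  DELTA_RHO_STEP, 0.0, np.inf, sse)
            p = p.replace(delta_rho=v)
            v, sse = _line_search(err_for("w"), p.w, W_STEP, 0.0, np.inf, sse)
            p = p.replace(w=v)
            v, sse = _line_search(err_for("c"), p.c, C_STEP, 0.0, 1.0, sse)
            p = p.replace(c=v)
            if sse >= sse_inner:
                break
        # (iv): refine period, overlap fraction and the coherent period count
        v, sse = _line_search(err_for("D"), p.D, D_STEP, 1e-6, np.inf, sse)
        p = p.replace(D=v)
        v, sse = _line_search(err_for("sigma"), p.sigma, SIGMA_STEP,
                              SIGMA_STEP, 1.0 - SIGMA_STEP, sse)
        p = p.replace(sigma=v)
        # N couples strongly to the contrast (peak height ~ N^2 delta_rho^2),
        # so each candidate N re-searches delta_rho before being judged
        best_n = (sse, p.N, p.delta_rho)
        for n_try in range(max(1, p.N - 2), min(30, p.N + 2) + 1):
            if n_try == p.N:
                continue
            p_try = p.replace(N=n_try)
            e0 = _scaled_sse(q, y, p_try)[0]
            def f(v, p_try=p_try):
                return _scaled_sse(q, y, p_try.replace(delta_rho=v))[0]
            dr, e = _line_search(f, p_try.delta_rho, DELTA_RHO_STEP, 0.0,
                                 np.inf, e0)
            if e < best_n[0]:
                best_n = (e, n_try, dr)
        sse, n_new, dr_new = best_n
        p = p.replace(N=n_new, delta_rho=dr_new)
        if sse >= sse_outer_start * (1.0 - 1e-12):
            converged = True
            break

    sse, K = _scaled_sse(q, y, p)
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else 1.0
    r2 = float(np.clip(r2, 0.0, 1.0))
    rmse = math.sqrt(sse / q.size)
    return StepFitResult(
        params=p,
        r_squared=r2,
        rmse=rmse,
        n_iterations=n_iter,
        fit_range=fit_range,
        converged=converged,
        scale=K,
        init_params=init,
    )


def sigma_landscape(
    profile: QProfile,
    fitted: StepFitResult,
    sigma_grid: Sequence[float],
) -> np.ndarray:
    """RMSE between data and model as sigma varies, all else frozen.

    Every other parameter — period, contrast, damping and the overall scale
    — is held at its fitted value, so the curve isolates the sensitivity of
    the fit to the gap/overlap partition.  Report against the gap fraction
    ``1 - sigma``; by Babinet's principle the noiseless landscape is
    symmetric under sigma <-> 1 - sigma.
    """
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if np.any(sigma_grid <= 0) or np.any(sigma_grid >= 1):
        raise ValueError("sigma_grid must lie strictly inside (0, 1)")
    sub = profile.crop(*fitted.fit_range)
    q, y = sub.q, sub.intensity
    out = np.empty(sigma_grid.shape)
    for i, s in enumerate(sigma_grid):
        m = forward_intensity(q, fitted.params.replace(sigma=float(s)))
        r = y - fitted.scale * m
        out[i] = math.sqrt(float(np.dot(r, r)) / q.size)
    return out
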