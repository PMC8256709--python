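# Methods

## Scientific setting

Type-1 collagen micro-fibrils are built from ~300 nm triple-helix molecules
packed in an axially staggered array. The stagger produces, along the fiber
axis, an alternation of *overlap* regions (higher molecular packing, length
σ·D of the period) and *gap* regions (lower packing, length (1−σ)·D), with
an axial repeat D ≈ 63–67 nm that depends on hydration and chemical state.
In small-angle X-ray scattering this periodicity appears as a series of
meridional Bragg peaks at qₙ = 2πn/D; in wide-angle scattering the
equatorial ~4 nm⁻¹ peak tracks the ~1.5 nm lateral spacing between triple
helices and the meridional ~22 nm⁻¹ peak the ~0.286 nm axial rise per amino
acid (one third of the 0.86 nm helix unit height). Non-enzymatic glycation
(sugar cross-linking) redistributes electron density between gap and
overlap and shifts these length scales; the pipeline quantifies those
changes from raster scans of 1D scattering curves.

Throughout, q is in nm⁻¹ and length scales are reported as d = 2π/q.

## The two-level axial density model (`stepmodel`)

One period of the axial excess electron density (relative to the embedding
matrix) is approximated as a two-level step: ρ₁ = ρ_ave + Δρ over σD
(overlap) and ρ₂ = ρ_ave − Δρ over (1−σ)D (gap). In the kinematic
approximation the meridional intensity from N coherently interfering
periods factorizes as

    I(q) ∝ M(q) + Damp(q; w, c) · F(q) · S_N(q)

with

* interference (finite grating): S_N(q) = sin²(NqD/2) / sin²(qD/2), equal
  to N² at the Bragg condition qD = 2πn (evaluated by its limit there);
* single-period fluctuation factor:
  F(q) = (Δρ²/q²)·|2e^{iqσD} − 1 − e^{iqD}|²/4, which at the Bragg
  positions reduces to (4Δρ²/q²)·sin²(πnσ) — even orders are suppressed as
  σ → 0.5, which is the basis of the asymmetry statistic below;
* monotone term M(q) = ρ_ave²/(2q²): the period-average density
  contributes a rapidly fringing term whose unresolved mean decays as
  1/q²; it is carried on the same normalization as F so that the fitted
  Δρ/ρ_ave ratio remains physical;
* damping Damp(q; w, c) = c + (1−c)/(1 + (qw/2π)²): a Lorentzian with a
  high-q floor c, absorbing the finite sharpness of real gap/overlap
  interfaces and multiple-scattering/defect losses. w carries nm units;
  w = 0 or c = 1 disables it. An alternative max(Lorentzian, c) form was
  rejected as non-smooth.

Babinet ambiguity: σ and 1−σ produce identical |F(q)| for every q, so
meridional intensities alone cannot distinguish a density profile from its
complement. Tests and reported landscape minima treat the two mirrors as
equivalent.

### Fitting

`fit_profile` is a staged coordinate descent on fixed parameter grids:

1. Initialization from the data: D from the detected Bragg-peak positions
   (the strongest peak is anchored at order 3 or 5, integer orders
   assigned, through-origin regression of qₙ vs n); N from the FWHM of the
   sharpest peak via N = round(5.566/(D·FWHM)) — 5.566/(ND) is the FWHM of
   the sinc²-like grating peak — clamped to [3, 30]; σ = 0.46 (the nominal
   overlap fraction of hydrated collagen), ρ_ave = 1, Δρ = 0, w = c = 0.
2. Contrast: Δρ walked in steps of 0.001 while the squared error decreases.
3. Damping: w in steps of 0.1 nm, c in steps of 0.01; stages 2–3 alternate
   until the error stabilizes.
4. Refinement: D on a 0.1 nm grid and σ on a 0.001 grid; then N is
   refined over ±2 candidate integers, each judged after re-searching Δρ
   (N and Δρ are strongly coupled through the N²Δρ² peak weight, so a
   lone integer step in N can never improve a Δρ-adapted state).
5. The whole cycle repeats until the error stops decreasing, capped at ten
   outer iterations; reaching the cap sets `converged = False`.

The overall intensity scale K (profiles are in arbitrary counts) is a
linear nuisance parameter solved in closed form, K = ⟨m,y⟩/⟨m,m⟩, at every
error evaluation; ρ_ave stays pinned at 1 and Δρ is reported relative to
it. The fit is unweighted least squares. Data before the first scattering
peak (dominated by the central scatter / beamstop region) are excluded
unless an explicit fit range is given. Ties in a line search keep the
incumbent value, biasing toward the initialization. Goodness of fit is
R² = 1 − SS_res/SS_tot over the fit range (clipped to [0, 1] against
floating-point underflow), and RMSE is reported alongside.

`sigma_landscape` freezes every fitted parameter including K and sweeps σ,
reporting RMSE against gap fraction 1−σ. On noiseless synthetic data its
global minimum sits at the planted gap fraction (or its Babinet mirror)
within one grid step.

### Peak detection

Bragg peaks are found on the q²·I(q) curve (removing the 1/q² envelope),
lightly Savitzky–Golay smoothed (window ≈ 2% of the points, order 2),
with `scipy.signal.find_peaks`; detections below 8% of the strongest
prominence are discarded. If two detections round to the same integer
order, the taller wins.

## Per-frame peak maps and histograms (`peakfit`)

At each of four fixed windows — waxs_equatorial q ∈ [2.5, 6.0] (d ≈ 1.5 nm),
waxs_meridional q ∈ [19, 25] (d ≈ 0.286 nm), saxs_meridional_9th
q ∈ [0.80, 0.95] (ninth order of D, d ≈ 7.2 nm), saxs_equatorial_fibril
q ∈ [0.03, 0.08] (fibril diameter 100–150 nm, inter-fibril 2π/q
convention) — each frame is fitted with a Gaussian on an A·q⁻ⁿ background
plus a constant floor (the floor covers the detector/dark level; the
exponent is bounded to [0, 6]). The optimizer is lmfit's trust-region
`least_squares` backend, which handles the bounded, poorly scaled
background parameters far more reliably than MINPACK on these curves. A
fit is significant when the amplitude exceeds both 3× the residual RMSE
and 10⁻³ of the window maximum (the latter keeps a numerically perfect
background fit from promoting a vanishing peak). Per-pixel failures are
recorded rows, never dropped.

The up-to-4131 per-pixel positions of one sample are condensed by a
Gaussian mixture (scikit-learn, 1–3 components, chosen by BIC; histograms
binned by the Freedman–Diaconis rule for display). The sample's length
scale is the area-weighted mean of component positions,
Σwᵢmᵢ/Σwᵢ, and its uncertainty the identically weighted mean of component
FWHMs. Histograms are built over q with d = 2π/q derived.

## Bragg-order asymmetry (`asymmetry`)

After indexing the meridional orders (same detection and through-origin
regression as above; D_est = 2π/slope), each order's intensity is
integrated over ±1.5 FWHM above a local linear background drawn between
the window edges. The asymmetry value is

    A = Σ_{even n ≥ 4} Iₙ / Σ_{odd n ≥ 3} Iₙ,

orders above max_order (default 9, the highest order the data resolve;
orders 1–2 are excluded by the definition and are beamstop-prone) are
dropped. A = 0 for the symmetric σ = 0.5 density, grows as σ moves away
from 0.5, is invariant under intensity rescaling and under σ ↔ 1−σ, and is
computed on the per-sample average profile. Both sums use integrated areas
by default so the ratio compares like with like; a `mode="height"` switch
uses background-subtracted heights for the odd orders instead. No
damping/Lorentz correction is applied before integration.

## Segmentation screen (`segmentation`)

A simplified signal-classification workflow: each curve is log₁₀
transformed (SAXS spans decades; WAXS stays linear), shifted to a zero
minimum, normalized to unit total, decomposed by PCA into 3 components,
and clustered by seeded k-means (k = 4 default, 20 restarts). Each
subset's representative is its medoid (the member closest to the centroid
in PC space); subset abundances and per-pixel PC scores are returned. The
screen is a quality-control step, not a claim of equivalence with any
published classification implementation.

`flag_outlier_samples` computes each sample representative's correlation
distance (1 − Pearson r) to a control profile and flags samples more than
5 median absolute deviations above the median distance (with a small MAD
floor so an identical population never flags). This mirrors the exclusion
of anomalous profiles — dried or badly prepared tissue with shifted
periodicity and intensity — from downstream analysis.

## Synthetic data (`synth`)

The generator emulates the statistical structure of the beamline scans so
the full pipeline runs without experimental data:

* SAXS: the forward model above, scaled so the expected counts at the
  third-order Bragg peak equal `count_scale` (default 10⁴; the third order
  is the strongest peak inside the fitted range), plus a constant detector
  floor, with optional Poisson counting noise and a √counts uncertainty
  column.
* WAXS: Gaussian peaks (defaults at 4.0 and 22.0 nm⁻¹) on an A·q⁻ⁿ + floor
  background, same noise model.
* Scans: default 81 × 51 = 4131 pixels at a 50 µm raster step. Parameters
  vary across the grid only through smooth per-parameter maps or explicit
  rectangular outlier regions — emulating laterally homogeneous tissue
  with localized anomalies. Pixel (row, col) draws from an independent
  stream seeded by (master seed, row, col), so any pixel is reproducible
  in isolation and identical seeds give bit-identical scans.
* Default q grids: SAXS 0.05–1.2 nm⁻¹ (1000 points; brackets orders 1–12
  of D ≈ 65 nm), WAXS 2–28 nm⁻¹ (1500 points; ≥10 points per peak FWHM).
* The canonical control truth is D = 65.5 nm, σ = 0.46, Δρ = 0.08, N = 10,
  w = 9 nm, c = 0.05 — the hydrated, non-glycated regime.

What the generator does **not** emulate: 2D detector geometry,
polarization and solid-angle corrections, azimuthal anisotropy of fiber
orientation, sample absorption, or instrument background drift. Passing
tests therefore demonstrate the correctness of the analysis chain on data
obeying the model assumptions, not robustness to every artifact of real
frames. Counting statistics are a fixture choice: the incident-count level
of the real experiment is not emulated, and at `count_scale` 10⁴ the
per-pixel ninth-order SAXS peak (~tens of counts over hundreds of
background counts) sits below the 3×RMSE significance rule for most
pixels — the orchestrator records that as "summary unavailable" for the
window rather than inventing a value, while the same feature is fully
measurable on noiseless or averaged curves.

## Orchestration (`pipeline`, `cli`)

`run_sample` applies, per sample: segmentation screen → per-pixel peak
maps and histogram summaries for each applicable window → step-model fit
of the average SAXS profile → asymmetry on the same average → σ landscape
around the fit. Windows outside the measured q range are skipped as not
applicable; stage exceptions are recorded per stage and do not abort the
run. All defaults (σ₀ = 0.46, ten iterations, steps 0.001/0.001/0.1
nm/0.1 nm/0.01) live in `RunConfig`, which round-trips losslessly through
JSON. The `fibrilsaxs` CLI exposes one subcommand per stage plus
`simulate` and `run-sample`; 2D frames enter only through
`fold_azimuthal`, which regroups a plain intensity array with beam-center,
pixel-pitch, distance and wavelength metadata into per-segment radial
profiles (segment 0 starting at the +horizontal axis, counter-clockwise —
a declared convention).

## Numerical choices and limitations

* Removable singularities of S_N are evaluated by the limit
  N·cos(Nx)/cos(x) when |sin x| < 10⁻⁹.
* The landscape and all fits operate on the q range from (just before) the
  first detected peak upward; everything below is excluded.
* Problem sizes in the test-suite and acceptance runs (scan grids of
  4×4–12×12 pixels, 25 noisy fit replicates, 50 mixture replicates at
  n = 4131) were chosen as the smallest sizes at which the statistical
  assertions are stable.
* The fit cannot resolve the σ ↔ 1−σ ambiguity or separate w from c when
  damping is weak (several (w, c) pairs describe a noiseless curve equally
  well); only Δρ, D, σ and N are treated as quantitatively recovered.
* `summarize_histogram` fits the mixture to the raw positions, not to the
  binned histogram, so bin width never biases the summary.
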