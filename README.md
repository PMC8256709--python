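# fibrilsaxs

Quantitative analysis of scanning SAXS/WAXS microscopy data from type-1
collagen tissue, aimed at studies of glycation (sugar cross-linking, the
process underlying diabetic and age-related changes in connective tissue).
A raster scan of a tissue sample yields thousands of 1D scattering curves;
this package turns them into a handful of structural parameters of the
collagen fibril and flags anomalous data on the way.

## What it computes

Collagen micro-fibrils repeat along the fiber axis with a period
D ≈ 63–67 nm, each period split into an *overlap* region (fraction σ,
higher electron density ρ₁ = ρ_ave + Δρ) and a *gap* region (fraction 1−σ,
density ρ₂ = ρ_ave − Δρ). The meridional SAXS intensity from N interfering
periods is modelled as

    I(q) ∝ M(q) + D(q; w, c) · F(q) · S_N(q)

where S_N(q) = sin²(NqD/2)/sin²(qD/2) is the finite-grating interference
term (→ N² at the Bragg condition q = 2πn/D), F(q) is the two-level
single-period structure factor — at the Bragg orders proportional to
sin²(πnσ)/n², so even orders vanish as σ → 0.5 — M(q) ∝ ρ_ave²/q² is the
monotone contribution of the average density, and D(q; w, c) is a
Lorentzian damping with high-q floor c. The package provides:

* **stepmodel** — the forward model and a staged coordinate-descent fit
  (contrast Δρ in 0.001 steps, damping w/c in 0.1 nm/0.01 steps, then D
  and σ on 0.1 nm/0.001 grids, at most ten cycles) with closed-form
  intensity scaling, R² accounting, and the RMSE-vs-gap-fraction
  landscape around a fit.
* **peakfit** — per-frame Gaussian-on-q⁻ⁿ peak fits at the four collagen
  length scales (~1.5 nm lateral spacing, ~0.286 nm axial rise, ninth
  order of D at ~7.2 nm, 100–150 nm fibril diameter), and per-sample
  condensation of the up-to-4131 per-pixel positions via BIC-selected
  Gaussian mixtures with area-weighted summary position and FWHM.
* **asymmetry** — meridional Bragg-order indexing, period extraction by
  through-origin regression, and the even/odd asymmetry value
  Σ_{even n≥4} Iₙ / Σ_{odd n≥3} Iₙ, the scalar that tracks deviation of
  the axial density from the symmetric hydrated state.
* **segmentation** — PCA (3 components) + k-means screening of a scan
  into subsets with medoid representatives, and correlation-distance
  flagging of anomalous samples against a control.
* **synth** — a ground-truth-labelled generator of SAXS/WAXS profiles and
  full 81 × 51 raster scans (Poisson counting noise, smooth parameter
  maps, planted outlier regions), so the entire pipeline is testable
  without beamline data.
* **io / pipeline / cli** — plain-text profile and scan-directory formats,
  azimuthal regrouping of 2D frames, a JSON run configuration, the
  per-sample orchestrator, and a `fibrilsaxs` command-line interface
  (`simulate`, `fit-profile`, `landscape`, `scan-peaks`, `histogram`,
  `asymmetry`, `segment`, `run-sample`).

Units: q in nm⁻¹ everywhere; length scales reported as d = 2π/q.
See `docs/methods.md` for the model, its assumptions and limitations.

## Worked example

Fit a synthetic control-tissue curve (D = 65.5 nm, σ = 0.46, Δρ = 0.08,
N = 10, Poisson noise at 10⁴ counts on the third-order peak):

```python
from fibrilsaxs import (default_truth, generate_saxs_profile, fit_profile,
                        index_orders, asymmetry_value)

truth = default_truth(seed=1)
profile = generate_saxs_profile(truth, noise="poisson")

fit = fit_profile(profile)
print(f"D        = {fit.params.D:.2f} nm")
print(f"sigma    = {fit.params.sigma:.3f}  (gap fraction {1-fit.params.sigma:.3f})")
print(f"delta_rho= {fit.params.delta_rho:.3f}  (relative to rho_ave = 1)")
print(f"N        = {fit.params.N} periods")
print(f"R^2      = {fit.r_squared:.3f} in {fit.n_iterations} iterations")

table = index_orders(profile)
asym = asymmetry_value(table)
print(f"indexed period D_est = {table.D_est:.2f} nm")
print(f"asymmetry value      = {asym.value:.3f}")
```

prints

```
D        = 65.48 nm
sigma    = 0.460  (gap fraction 0.540)
delta_rho= 0.079  (relative to rho_ave = 1)
N        = 10 periods
R^2      = 0.999 in 2 iterations
indexed period D_est = 65.48 nm
asymmetry value      = 0.227
```

The fit recovers the planted period to 0.02 nm and the overlap fraction
exactly; Δρ comes back within ~1% of the planted contrast. The asymmetry
value 0.227 is the even/odd intensity ratio of orders 3–9 — it would be 0
for a perfectly symmetric (σ = 0.5) axial density and grows as glycation
pushes the gap/overlap partition away from symmetry. Note σ = 0.46 and
σ = 0.54 are indistinguishable here (Babinet ambiguity): complementary
densities scatter identically in the meridional orders.

The same from the shell:

```sh
fibrilsaxs simulate --out scan/ --seed 1
fibrilsaxs run-sample --scan scan/ --out report/
```

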