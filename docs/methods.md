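# Methods

## The survival model

The package models clonogenic survival of irradiated cells with a modified
linear-quadratic (MLQ) form in which the quadratic term is scaled by a
Lea–Catcheside protraction factor `G ∈ (0, 1]` accounting for first-order
repair of sub-lethal damage (SLD) during delivery. For a constant dose rate
over `θ` minutes and a single characteristic repair time `t0`,

    G(θ, t0) = 2(t0/θ) [1 − (t0/θ)(1 − e^(−θ/t0))],

which is the closed form of the double integral
`(2/θ²) ∫₀^θ dt ∫₀^t dt′ e^{−(t−t′)/t0}`. SLD repair is bi-phasic: a
fraction of sub-lesions repairs with a fast time constant and the rest with
a slow one, so the working factor is the convex combination
`G_R = a_f G(θ, t0f) + a_s G(θ, t0s)` with proportions depending on the
radiation's LET class (low-LET photons repair predominantly fast; high-LET
products predominantly slow). `θ = 0` encodes an acute exposure, `G = 1`.

The mixed BNCT field carries three terms — boron capture (α + ⁷Li), neutron
(proton and recoil), photon — each with its own `(α, β)` and LET class, plus
pairwise quadratic cross terms `2 G_ij √(β_i β_j) D_i D_j` expressing
synergy between simultaneously accumulated sub-lesions. The photon
isoeffective dose `D_IsoE` is defined by survival equality with the
reference photon radiation and is computed by the cancellation-free
quadratic inversion `D = 2E / (α_R + √(α_R² + 4 β_R G_R E))`, where `E` is
the mixed-field log-kill. This form is exact in both the `β_R → 0` and
`α_R → 0` limits and avoids the loss of precision of the textbook
`(−α + √(α² + 4βGE)) / 2βG` when `βG` is tiny (e.g. a fitted β that landed
on its zero bound). When the reference delivery is itself protracted at a
fixed dose rate, `G_R` depends on the solution through `θ_R = D/rate`; the
inversion is then iterated to a relative tolerance of 1e-8 (it converges in
a handful of iterations because `G_R` varies slowly with `D`).

Cross-term protraction factors have no canonical definition for components
of different LET classes. Since all components are delivered simultaneously
over the same `θ`, the package computes each cross factor with the
dual-kinetics formula using the arithmetic mean of the two components'
fast-repair proportions. At the delivery times of interest (10–35 min) every
G lies in 0.96–0.99, so any reasonable alternative rule changes results by
well under 1%.

## Key parameters

| quantity | units | default | notes |
|---|---|---|---|
| t0f, t0s | min | 91, 1238 | fast/slow SLD repair times (U87 foci fit) |
| fast fraction, low LET | — | 0.77 | bi-exponential weight c |
| fast fraction, high LET | — | 0.2 | literature split for densely ionizing radiation |
| photon α, β (Co-60) | Gy⁻¹, Gy⁻² | 0.21, 0.02 | reference radiation for clinical dosimetry |
| photon α, β (x-ray) | Gy⁻¹, Gy⁻² | 0.46, 0.03 | low-energy (60–80 keV) alternative reference |
| neutron α, β | Gy⁻¹, Gy⁻² | 0.5, 0.5 (Co-60 ref) / 0.1, 0.5 (x-ray ref) | beam-only fit |
| boron α, β | Gy⁻¹, Gy⁻² | 3.0, 0 | β sits on its non-negativity bound |
| clinic weights | — | CBE 3.8, RBE 3.2, photon 1 | gliosarcoma-derived fixed factors |
| endpoint survival | — | 0.01 | RBE₁%/CBE₁% convention |
| boron concentration | ppm | 40 (tumor), 13.6 (brain) | scales the per-ppm boron dose grid |
| prescription | Gy(RBE) | 2.5 to ≤50% of brain | sets the irradiation time |

Endpoint RBE/CBE factors are ratios of inverted doses: the reference curve
(acute by default — the derived factors assume an idealized instantaneous
photon exposure; a constant-rate mode is available) over the isolated
component curve with its own `(α, β)` and its 10-minute high-LET protraction
factor.

## Fitting

All survival fits minimize weighted residuals in log-survival, where the MLQ
exponent is linear in the parameters being estimated; weights are the
propagated uncertainties `σ_lnS = σ_S / S`. Optimization is bound-constrained
trust-region least squares (lmfit) with multi-start initialization; input
points are canonically sorted first, so results are exactly independent of
input order. Non-negativity bounds on all `α, β`; a parameter within 1e-7 of
its bound is flagged. The covariance is left unscaled when point
uncertainties are supplied (they are absolute Poisson counting errors, not
relative weights) and scaled by the reduced chi-square otherwise.

The reference curve is fitted first; its `(α, β)` are then frozen as the
photon component while the beam-only and BPA-BNCT curves are fitted
simultaneously, sharing the neutron parameters, with the boron parameters
informed only by the BNCT points. β_B characteristically lands on the zero
bound — the boron-capture products act as pure single-hit killers.

The bi-exponential foci-decay fit uses a multi-start grid over both time
constants (the objective is shallow in the slow constant; its fitted
uncertainty is of the order of the estimate itself), with fast/slow labels
normalized after the fit. Confidence intervals default to linearized
normal-theory half-widths at 68%; a seeded parametric bootstrap is provided
as a cross-check and agrees with the linearized intervals to ~20% on
well-conditioned fits.

## Synthetic data

The generators are pure functions of (inputs, seed) and emulate the
statistical structure of the real experiments:

* **Clonogenic assays** — colony counts are Poisson with mean
  `seeded × PE × S(dose)`; surviving fractions are normalized to a zero-dose
  control (plating efficiency PE = 0.8 by default), and uncertainties
  propagate both counting errors. The boron dose carries a 5% relative
  Gaussian perturbation representing the boron-concentration measurement,
  the dominant dose uncertainty. Default designs mirror the study
  conditions: photon curves at 1–8 Gy (~1 Gy/min source, treated as acute),
  thermal-column irradiations of 10 min at four reactor powers
  (7.5/30/100/250 kW dose scaling) with a configurable 10% photon
  contamination, and seeding escalated with dose so expected colony counts
  stay countable.
* **Foci series** — bi-exponential intensity plus Gaussian noise, clipped
  positive and renormalized to the first sample.
* **Phantom fields** — a 24³-voxel (2.5 mm) water-equivalent block, each
  component decaying exponentially with depth (boron/thermal 30 mm, fast
  neutron 12 mm, photon 70 mm) under a Gaussian lateral beam profile
  (σ = 15 mm), 1% multiplicative noise emulating Monte Carlo statistics, a
  10 mm-radius spherical tumor at 20 mm depth, and a per-ppm boron grid.
  Surface rates were chosen once so that, after scaling the irradiation time
  to the normal-tissue prescription, the tumor lands in the clinically
  reported range of tens of Gy-eq.

What the generators do **not** emulate: anatomical geometry, neutron
transport physics (no build-up, scatter tails or spectral shifts),
cell-cycle or hypoxia effects on survival, non-Poisson colony-counting
biases, and boron micro-distribution. Passing tests therefore demonstrate
the correctness and statistical calibration of the *pipeline*, not the
fidelity of any particular clinical dose distribution; published
patient-level absolute doses are out of reach without the clinical geometry
and transport calculations and are deliberately not reproduced.

## Reporting conventions

DVHs are cumulative volume-fraction histograms over ROI voxels with 256
uniform bins from 0 to just above the ROI maximum (start exactly at 1, end
exactly at 0); `Dmean` is the unweighted mean over mask voxels. The
irradiation time satisfying "no more than L Gy(RBE) to a fraction v of the
organ" is closed-form — the RBE-weighted dose is linear in time, so
`t = L / q` with `q` the `(1−v)` quantile of the per-minute weighted rate
(the median rate for v = 0.5). Percent differences between parameter-set
arms use the glioblastoma-parameter value as the denominator,
`100 (ref − other)/ref`, rounded to integer percent for reporting; doses are
reported to 0.1 Gy-eq.

## Numerical notes and limitations

* `G(θ, t0)` switches to a 4-term series below `θ/t0 = 1e-3` to avoid
  cancellation; the two branches agree to 1e-9 at the seam and the closed
  form matches direct numerical integration to better than 1e-6 over
  θ ∈ [0.1, 10⁴] min.
* The acute closed form and the survival-equality root agree to 1e-8
  relative over randomized dose/parameter combinations (tested at n = 1000).
* Degenerate inputs: zero total dose maps to zero equivalent dose; an empty
  ROI, non-co-registered grids, a rate-mode field without an irradiation
  time, or a zero weighted rate at the prescription level raise typed
  errors rather than returning numbers.
* The slow repair constant is weakly identified from 24-hour foci series
  (noise at the 5% level allows order-of-magnitude excursions); estimates of
  `t0s` should be read together with their intervals, and downstream G
  factors are insensitive to it at short delivery times.
* Tumor-cell survival parameters only: normal-tissue response is handled
  exclusively through user-supplied fixed weights, not an isoeffective
  model.
* The pipeline maps the four treatment-planning grids to the three model
  terms by summing the thermal-capture and fast-recoil neutron grids before
  conversion.
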