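# Methods

## Problem and data

The package models MBCOMT specific activity (nmol/h/mg protein) as a
function of three induction-phase factors in *Pichia pastoris* fed-batch
bioreactor cultures: methanol constant feed rate (mL/L/H), induction
temperature (°C) and DMSO concentration (% v/v). The calibration data are
the 27 recorded fermentations bundled as `data/calibration_campaign.csv`: 17 runs of a
face-centered central composite design over (1–3, 20–30, 4–6), four groups
of model-guided iteration runs (runs 18–20 at (1, 22.5, 6); 21–22 at
(2.9, 30, 6); 23–24 at (3, 30, 6); 25–26 at (2.5, 30, 6)) and a final
validation run (27, prediction only). Run 8 is flagged as a model outlier
(observed 153.9 against a predicted 358.1) and is excluded from every
default calibration subset but kept for diagnostics. Run 27 has no measured
activity and is never calibrated on.

## Design construction

`build_ccd` emits the 2^k factorial corners, 2k axial points and n_center
center replicates in that fixed order. The axial distance is α = 1
(face-centered): the recorded design uses exactly three levels per factor,
and a rotatable α would introduce levels the campaign never ran. Row order
is bookkeeping only; nothing downstream depends on it. Coded and natural
units are related by the affine map `coded = (natural − mid)/((high −
low)/2)`; the map never clamps, because legitimate off-design inputs occur
(e.g. 22.5 °C in the first iteration group).

## Network and training

The response surface is a fully connected 3/2/1 network — tanh hidden
units, linear output, 11 free parameters. Tanh/linear is the conventional
pairing for this architecture; it is declared here rather than inferred,
and it is consistent with a smooth optimum partly interior to the box.
Inputs and the response are min–max scaled to [−1, +1] from the
calibration data; training a tanh network on raw activities of order
100–400 stalls in saturation. A variable with zero range is padded by 0.5
on each side so it maps to 0.

Training minimizes the scaled-response SSE by Levenberg–Marquardt:

* initial damping λ = 0.01 (the study's "learning rate"),
* rejected steps multiply λ by 1.05 (its "ratio to increase learning
  rate") and are retried,
* accepted steps divide λ by 10 — the decrease ratio is not fixed by the
  study; 10 is the conventional choice and affects convergence speed, not
  the fixed point,
* at most 1,000 epochs; stop early when the gradient norm falls below
  1e-8, an accepted step improves the SSE by less than 1e-12, or λ
  escalates past 1e10 (no descent direction — the best iterate is
  returned).

A fit is reported as *converged* when its final gradient norm is below the
gradient tolerance; an SSE stall without a small gradient is not
convergence. Singular normal equations are handled by escalating λ, never
fatally. The hot loop is numba-compiled, with an explicit pivoted Gaussian
solve so singularity is a recoverable flag rather than an exception.

The objective is nonconvex, so the public fit is a seeded multi-restart:
initial parameters uniform on [−0.5, +0.5], drawn sequentially from one
generator so restart sequences are nested (more restarts can only improve
the best SSE) and fully reproducible. The default 200 restarts makes the
selected minimum-SSE model stable across seeds on the bundled data (scaled
SSE 0.2427 for every seed tried). Model files (YAML) store weights,
scaling bounds, config and seed, enough to reproduce predictions
bit-exactly.

## A structural property of the 2-hidden-unit surface

The network output depends on x only through the two projections w₁ᵀx and
w₂ᵀx: with three inputs the fitted surface is *exactly constant* along one
direction of input space (a rank-2 ridge function). Consequences:

* The box argmax always lies on the boundary of at least one coordinate
  combination; a surface maximum interior in all three factors cannot
  occur. The study's own optimum — temperature and DMSO on their upper
  bounds, methanol interior — is exactly the geometry this model class
  produces.
* When the true underlying surface has a fully interior optimum, the
  argmax of the fitted surface is undetermined along the flat direction:
  simulated recovery experiments can pin down the attainable maximum
  *value* (relative error ≲ 10 % under calibration-like noise) but not all
  three argmax *coordinates*. Recovery tests therefore assert coordinate
  recovery only for teachers the model class can represent (where it is
  exact) or with boundary optima, plus a frozen Monte-Carlo regression
  bound for the noisy interior case (median coded-space argmax error ≤
  1.25; measured 0.99 over an 11-seed baseline under study-like
  conditions).

## Surface maximization and the campaign loop

`surface_max` evaluates the fitted surface on a full lattice (default 101
nodes per axis, so the methanol spacing 0.02 mL/L/H is finer than the
reported optimum's resolution), takes the best node with ties broken by
lowest lattice index, then polishes by bounded L-BFGS-B ascent, keeping
the polished point only if it improves. The search box defaults to the
design ranges — extrapolating a 2-hidden-unit network beyond its
calibrated box is unsupported.

`run_optimization_loop` alternates fit → argmax → propose replicates →
append → refit. In *replay* mode the recorded iteration groups are
appended verbatim, one group per iteration, reproducing a historical
campaign exactly (including its stopping point); the convergence tolerance
(0.05 coded units, half the smallest printed input resolution) stops the
loop only in *simulate* mode, where new observations come from a teacher
surface plus noise. Intermediate surfaces fitted to few points (16–23
observations for 11 parameters) are near-interpolants and can predict
unphysically large maxima between design points; only the final,
fully-calibrated model is interpreted.

Diagnostics regress predicted (y) on observed (x) — the slope target is
sensitive to this orientation, so it is fixed; R² is the squared Pearson
correlation. Outlier-flagged records are listed but excluded from the
line. The bundled table's recorded observed/predicted pairs reproduce the
study's reported slope 0.9064 and R² 0.97161 to printed precision. The
refit model (global minimum-SSE) fits the data more tightly than the
published one, so its slope ≈ R² ≈ 0.975; a slope in the published band
0.9064 ± 0.05 would require a deliberately looser fit than the
multistart-minimum procedure produces, and the corresponding acceptance
test documents this by failing.

Two fold-improvement baselines coexist in the study's own reporting
(384.8/252.5 ≈ 1.52 vs 384.8/243.8 ≈ 1.58); `fold_improvement` takes the
baseline explicitly and reconciles nothing silently. The shake-flask
baseline is 60.25 nmol/h/mg.

## qPCR copy number

Primer efficiency is the least-squares slope m of Ct against log₁₀
template in a serial dilution, E = 10^(−1/m); |m| < 1 (efficiency above
10) is rejected as implausible. `Ravg = E^(−ΔΔCt sample) / E^(−ΔΔCt
reference)` uses a single mean efficiency per the defining equation; when
the two primer pairs differ (measured 1.87–1.94), the mean of the two is
the default and per-pair efficiencies are an explicit advanced usage.
Cassette count is round(Ravg) − 1 (endogenous copy subtracted); rounding
is half-away-from-zero, a declared choice since only integer results are
reported. Replicate Ct scatter propagates to a first-order Ravg interval.

Simulated recovery (`simulate_measurement`, Ct noise 0.1 cycles on the
target-sample reaction) is near-certain only at low dosage: exact recovery
requires Ravg within ±0.5 of n+1, i.e. |ε| ≲ 0.5/((n+1)·ln E) cycles, so
the rate falls from ~100 % at 1–2 copies through ~96 % at 3 to ~30 % at 20
copies. The suite asserts ≥ 95 % recovery for n ≤ 2 (1,000 replicates) and
monotone decay with n; a ≥ 95 % rate out to 20 copies is mathematically
impossible at this noise level, and the acceptance test stating it fails
accordingly.

## Synthetic data

The generator emulates the calibration campaign: a 17-run face-centered
CCD over the design ranges, homoscedastic Gaussian replicate noise with sd
11 nmol/h/mg — the sample sd of the three recorded center replicates
(252.5, 243.8, 230.3) — and truncation of negative draws at zero.
Teachers are either interaction-free quadratics (closed-form box argmax)
or stored networks. What it does not emulate: heteroscedastic or
run-order-correlated noise, biomass/methanol dynamics, or any time-course
structure; passing recovery tests therefore demonstrates correctness of
the fitting and optimization machinery, not that three factors suffice to
describe a real fermentation.

## Problem sizes and determinism

Default test and acceptance runs use 200 restarts for the headline refit
(~10 s), 15–50 restarts and 31–41-node grids for simulated campaigns, 11
seeded repetitions for the Monte-Carlo recovery baseline and 1,000
replicates for qPCR recovery. Every random draw flows from an explicit
integer seed; replaying any entry point with the same seed reproduces its
output exactly.
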