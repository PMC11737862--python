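# Methods

## Model

The node is an extended Wilson–Cowan pair: excitatory and inhibitory
populations with logistic input–output functions `F_E`, `F_I` that carry
separate thresholds (μ) and sensitivities (σ), a gain `G_E` multiplying
every excitatory input onto the excitatory population (recurrent drive and
external input alike), and optional inhibitory self-coupling `c_II` plus a
fraction `α` of the external drive delivered to interneurons. The defaults
(`c_EE=3.5, c_IE=3.75, c_EI=2.5, G_E=1, μ=1, σ=0.25, τ_E=2.5 ms,
τ_I=5 ms`) place the node's resonance in the low-gamma band: as external
drive grows it crosses an Andronov–Hopf bifurcation (at `I_ext ≈ 0.336`)
and oscillates near 40–45 Hz. The main-text configuration and all
closed-form solvers assume `c_II = 0, α = 0`; the numeric fixed-point and
nullcline machinery also handles `c_II > 0` (the inhibitory nullcline is
then solved by bisection, unique because its defining map is decreasing).

Rates are dimensionless activities in (0,1); time is milliseconds;
frequencies are reported in Hz via `1000·|Im λ|/(2π)` for eigenvalues in
1/ms. Integration is explicit Euler at `dt = 0.1 ms` by default. With
`dt ≤ min(τ_E, τ_I)` each update is a convex combination of the current
rate and a sigmoid output, so trajectories are confined to the unit square
structurally; larger steps are refused rather than clipped. Euler is the
only integrator on purpose: step-size sensitivity of the bifurcation
portrait is itself an object of study here, and an adaptive solver would
erase it.

## Fixed points and classification

Fixed points are roots of the difference between the two nullclines,
scanned over `rE ∈ [1e-6, 1-1e-6]` at step 1e-6 and refined by Brent's
method to 1e-12 (the scan alone would limit Jacobian accuracy). At a fixed
point the logistic slope simplifies to `r*(1-r*)/σ`, giving the Jacobian in
closed form. Regimes follow the trace/determinant taxonomy; a single
unstable spiral is labelled a limit cycle (the flux points inward on the
boundary of the unit square, so a periodic orbit exists), while a single
unstable *node* is deliberately labelled OTHER, as are tangent or
degenerate cases (|Tr| or |discriminant| below 1e-12), which are surfaced
rather than binned. Multi-root systems are judged relative to the fixed
point matching the requested target within 1e-6 (the scan resolution).

## Homeostatic solvers

Each mode inverts the fixed-point equation for its parameter(s); combined
modes add the equal-timescale constraint that every adapted parameter is
displaced from baseline by the same magnitude (sign chosen by whether the
parameter raises or lowers the excitatory rate). The coordinated
threshold/slope mode keeps `σ_E = K μ_E` with `K = σ_E0/μ_E0 = 0.25`, which
preserves the zero-input output `F_E(0)`. The `c_IE` solver computes the
inhibitory rate the excitatory nullcline requires at the target and inverts
`F_I`; when that required rate reaches 1 the mode is infeasible —
feedback inhibition saturates, which is why it breaks down at strong drive.

Dale's principle is enforced by *flagging*: a solution needing `G_E < 0`,
`c_EI ≤ 0` or `σ_E ≤ 0` is returned with `feasible=False` and the raw
values reported (these are the blank regions of the parameter maps). The
dynamic simulator is the one place constraints are clamped online instead,
because a running circuit cannot refuse a bound.

An experimental unequal-timescale variant generalizes the joint
`G_E + c_EI` constraint to displacements inversely proportional to each
mechanism's time constant (`ΔG_E = -(τ_c/τ_G)·Δc_EI`), reducing to the
standard form for equal timescales; the dynamic simulator accepts
per-parameter timescales and reproduces this closed form to 1e-13.

## Target mean rate

In the stable regimes the mean rate equals the fixed point; inside a limit
cycle it rises above it and no closed form exists for the cycle mean. A
target mean rate ρ is therefore mapped to parameters by bisection on the
candidate fixed point over (0,1) (endpoints offset by 1e-6 to avoid the
logit singularities): each midpoint is solved in closed form, simulated for
5 s, and the mean of the last 2 s steers the bracket, to `|⟨rE⟩-ρ| <
1e-10`. Monotonicity of the mean in the fixed point is assumed, as the
bisection requires; exhaustion of the bracket is reported as a diagnostic
instead of a silent mis-convergence. An iteration cap of 80 only bounds
runtime (2⁻⁸⁰ is far below any useful tolerance). Midpoints where the
solver is infeasible move the bracket according to which constraint fired
(gain/coupling/slope clamps and saturated required inhibition occur at
too-low targets; the reverse clamps at too-high ones).

## Frequency measurement

Peak frequency is the maximum of a single mean-removed rectangular-window
periodogram of `rE` over the final 3 s of a 5 s run, with a square pulse
(amplitude 1, width 1 ms) added to the drive at 3 s so that damped nodes
ring. The window deliberately includes 1 s of pre-pulse signal, matching
the mapping procedure; a strict post-pulse window is available by argument.
Bin width is ≈1/3 Hz; bins below 1 Hz are excluded as DC leakage; ties
break toward the lower bin. A variance below 1e-14 yields an undefined
(NaN) peak, not an error. The pulse width (1 ms, several integration steps
and short against both membrane constants) and its excitatory-only delivery
are package choices; both are configurable.

The analytic counterpart `f = 1000·√(Det - Tr²/4)/(2π)` is exact only in
the linear neighbourhood of a spiral. The test suite therefore validates it
with a small probe pulse (amplitude 0.01) at set-points 0.02–0.04 below
the Hopf boundary, where all eight modes agree within 1.5%; the amplitude-1
pulse of the mapping procedure drives excursions outside that
neighbourhood, where the measured peak legitimately deviates from the
eigenvalue prediction (and falls below it inside a developed cycle, whose
orbit slows away from the fixed point).

## Sweeps and boundaries

Bifurcation maps run over ρ in (0, 0.4] at step 0.005; the drive axis is
fully configurable (default 0–4 in steps of 0.25) and is always recorded in
output metadata. The analytic Hopf boundary bisects the target at which
the solved-fixed-point trace crosses zero (tolerance 1e-6); at onset the
mean rate equals the fixed point, so the boundary is identical on either
scale. The spiral-onset (node→spiral) boundary bisects the discriminant
zero the same way. The numerical boundary instead bisects the target
separating damped from sustained pulse responses — peak-to-peak `rE`
amplitude over the final second below 1e-4 versus above 1e-3, split at
their geometric mean, with in-between amplitudes flagged ambiguous — and
therefore inherits the Euler step bias: at coarse `dt` the limit cycle
extends to lower targets, most strongly under inhibitory-coupling
homeostasis, whose large solved couplings push the discrete spectral radius
past 1 (`1 + dt·Tr + dt²·Det > 1`) well below the analytic boundary. The
amplitude thresholds are package choices. The boundary search scans upward
at step 0.01 and refines the first damped→sustained pair, staying clear of
the multistable region at high targets where trajectories from rest escape
to a saturated state.

## Dynamic homeostasis

The slow counterpart co-integrates the node with integral control
`τ_homeo·dp/dt = ±(rE - ρ)` on each adapted parameter (σ_E slaved to
`K μ_E` every step). Defaults: `τ_homeo = 500 ms` (two orders above the
membrane constants), 200 s of simulated time at `dt = 0.2 ms`. The recovery
test uses `τ_homeo = 50 ms` — still an order of magnitude above τ_I — 
because the closed-loop gain of inhibitory-coupling homeostasis is tiny at
large couplings (`∂rE*/∂c_EI ≈ 3e-3` near its set-point), and the tail of
convergence at 500 ms would need >10⁶ ms. Convergence is declared when the
mean rate over the last 5% of the run is within 1e-4 of target.

Two honest limitations, both consequences of the model rather than the
implementation: (1) at `dt = 0.2 ms` the inhibitory-coupling set-point for
(ρ=0.1, drive 2) lies outside the explicit-Euler stability region, so the
dynamic loop settles at a step-shifted steady state a few units away from
the closed form — at `dt = 0.1 ms` the identical loop recovers it to
3e-4; (2) the `c_IE` loop started from rest at strong drive falls into the
saturated high-activity state (recurrent plus external excitation exceeds
what maximal inhibition can offset) and never reaches the target basin, the
same saturation that makes its closed-form solver infeasible at high drive.

## What the tests do and do not show

All inputs are generated by the package itself; there is no external data
and no noise, so every run is exactly reproducible. The deterministic node
omits stochastic drive, network coupling and delays: passing tests show the
solvers, classification, boundaries and measurements are internally
consistent and reproduce the published desk-scale quantities, not that the
homeostatic mechanisms behave identically in noisy or coupled settings.
Problem sizes used by the reproduction script: 5 s simulations at 0.1 ms;
target-rate scans at step 0.005; drive grids {0.5..4} (gain mode at target
0.1), {1..8} (inhibitory extremes; the frequency extreme is additionally
documented on the extended grid {1..10} × ρ {0.05..0.18}, where the
measured peak exceeds 250 Hz); corner grid ρ {0.005..0.05} × drive {1..8}
for the solved-coupling maximum.
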