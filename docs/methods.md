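# Methods

## The model

`epicard` implements a three-variable phenomenological model of the human
ventricular epicardial action potential, of the FitzHugh–Nagumo family in
the Rogers–McCulloch form. The state is the membrane potential V (mV),
a recovery variable u and a transient-outward gate w (both
dimensionless). The total ionic current is

    I_ion = g(u) · k · (I_exc + I_rec + I_to)

with the cubic excitatory current
`I_exc = c1 (V−B)(a − (V−B)/A)(1 − (V−B)/A)`, the recovery current
`I_rec = c2 u (V−B)` and the transient-outward current
`I_to = c3 w (V−B) s_u`, where `s_u = ((u_M − u)/u_M)²` is a quadratic
availability factor that extinguishes the notch at short diastolic
intervals. The shape factor

    g(u) = (γ0 + γ1 u) · (1 − tanh(α(u − θu)))/2 + g0

is large during the upstroke and relaxes to `g0` late in the action
potential; it multiplies the total current, the plateau rate and the w
rate within a single right-hand-side evaluation, which is what lets a
two-current cubic model produce a realistic spike-notch-dome morphology
and independent control of upstroke and repolarization speeds.

The gates obey

    du/dt = k e (x − u),      x = (V − B)/A
    dw/dt = k e_w (x − d_w w)

with the two-rate switch `e = e1` when `du/dt ≥ 0` (equivalently
`x − u ≥ 0`, which avoids any circularity) and `e = e2` otherwise.
During the upstroke `e1 = g·e10`, else `e10`; the upstroke is the
interval where both dV/dt ≥ 0 and dw/dt ≥ 0, implemented discretely from
the previous step's backward differences (flag false at t = 0).
`e_w = g·ew0` is not upstroke-gated. The w asymptote divisor is

    d_w = dw0 / s_u .

The divisor grows as u grows, so the w-asymptote `x/d_w` (and with it the
notch) shrinks during refractoriness; at `s_u = 0` the asymptote is taken
as exactly 0 rather than dividing. The alternative literal-product
reading `d_w = dw0·s_u` would have the opposite behaviour (a stronger
notch in refractory tissue) and is not used.

Rest is `(B, 0, 0)` and is an exact fixed point. The recovery variable
must stay below `u_M` (it reaches ≈0.49 in the simulated regimes); the
integrators assert `u < u_M` rather than clamping.

Default parameters (the published epicardial set): k = 1000 1/s,
c1 = 2.6, c2 = 1, c3 = 0.5, a = 0.18, A = 135 mV, B = −85 mV,
e10 = 0.0059, e2 = 0.015, γ0 = 8, γ1 = 20, α = 15, θu = 0.2, g0 = 0.1,
u_M = 0.58, ew0 = 0.04, dw0 = 0.6. Tissue coupling uses the monodomain
equation `∂V/∂t − ∇·(D∇V) = −I_ion + I_ext` with D = 1.171 cm²/s and
no-flux boundaries. The analytic excitation threshold is
a·A + B = −60.7 mV. Units project-wide: mV, s, cm; external currents in
mV/s (a 2 ms stimulus of amplitude S injects 0.002·S mV of direct
depolarization).

## Numerics

**Single cell (0D).** Forward Euler at dt = 0.01 ms — the model is
non-stiff at that step and this integrator doubles as the reference for
the tissue decoupling check (a cable with D = 0 reproduces it exactly,
bit for bit, in the explicit scheme).

**Tissue.** Node-centered grids, dx = 0.25 mm and dt = 0.1 ms by
default (2 cm cable: 81 nodes; 10×10 cm sheet: 401×401). Two schemes:

- `split` (default): Strang splitting — a Heun (RK2) reaction
  half-substep, a Crank–Nicolson diffusion solve over the full step, and
  a second reaction half-substep. Diffusion uses per-axis tridiagonal
  factors (ADI in 2D; the axis operators commute on a tensor grid) with
  a *blended mass operator* `M = tridiag(m, 1−2m, m)`, `m = 1/8`.
  Unconditionally stable in the diffusion step.
- `explicit`: forward Euler with the lumped conservative 3/5-point
  Laplacian, refused when dt exceeds dx²/(2·d·D).

The mass blend deserves a note. The AP upstroke lasts ~0.6 ms and the
depolarization front spans ~2 grid cells at 0.25 mm, so front speed is
dominated by the discrete dispersion of the spatial operator: the lumped
operator (m = 0) propagates at 51.8 cm/s at the default steps versus
~68.2 cm/s converged (a 14% change under step halving), the consistent
P1 mass (m = 1/6) overshoots to 72.4 cm/s, and the compact fourth-order
choice (m = 1/12) gives 64.9 cm/s. The blend m = 1/8 — the mean of the
lumped and consistent operators — sits where the leading dispersion
errors cancel for this front: CV changes by 0.02% under simultaneous
step halving (the package's accuracy gate, `convergence_gate`, adopts
the conventional <5% criterion and should be checked before trusting
quantitative output at a new resolution or parameter set). Both M and
the Laplacian stencil have unit/zero column sums, so the no-flux scheme
conserves the spatial mean of V exactly with the reaction disabled.

The Heun reaction substep is a fused numba kernel when numba is
importable (with an exactly-equivalent numpy fallback; the two agree to
~1e-16 and the numpy path is the oracle in the tests). Per-node upstroke
flags are updated once per full step from the step's net ΔV and Δw.

**Feature extraction.** APD90 is the time between interpolated upward
and downward crossings of −72.5 mV (90% repolarization). Upstroke
velocity is the maximum finite-difference dV/dt within ±5 ms of the
activation crossing. The notch is the first strict local minimum between
the upstroke peak and the later plateau maximum, searched within the
first 100 ms of the AP; monotonically repolarizing APs report no notch.
Conduction velocity uses two probes 0.5 cm apart symmetric about the
cable middle (distance over interpolated activation-time difference).

**Discretization sensitivity of the printed features.** At the default
steps the scheme reproduces the model's published tissue
characterization: APD90 267.3 ms (published 267.1), amplitude 125.1 mV
(125), max dV/dt 203.5 V/s (203), CV 68.45 cm/s (69). The phase-1 notch
is the exception: it measures 8.46 mV here versus 8.8 published, and
under step refinement it converges to ≈7.7 mV, so the printed figure
itself carries roughly +1 mV of discretization error from the original
cubic-FEM/BDF3 solver. A 2% agreement on the notch is therefore not
achievable with any consistent scheme at the default steps; the package
reports what it computes.

## Protocols

**Diastolic threshold.** Bisection (to 1% relative) on the amplitude of
a 2 ms pulse over the first 1 mm of the quiescent cable; capture means a
propagated AP at the cable middle. The isolated-cell variant requires a
regenerative overshoot above 0 mV. All pacing uses twice this threshold
(the 2D S2 uses three times).

**S1-S2 restitution.** Ten conditioning beats at CL = 1 s, then one
premature S2 per trial, with coupling intervals descending in 5 ms steps
from steady APD + 300 ms until capture failure; the conditioned state is
cached so each trial re-runs only the final segment. DI = S2 activation
minus previous repolarization at mid-cable; APD and CV from the S2 beat.

**Dynamic (steady-state) restitution.** Continuous pacing, 6 beats per
cycle length (sufficient for steady state in this memory-free model),
CL descending 1200→400 ms in 100 ms steps, →300 ms in 20 ms steps, then
5 ms steps until 2:1 block (mid-cable activation count below stimulus
count). Measurements on the last beat of each CL. The protocol sustains
1:1 down to CL 265 ms here (published 270 — within the 5 ms schedule
bin); the curve point at CL 270 reproduces the published endpoint
triplet (DI 51.25/51, APD 218.7/219, CV 31.0/31).

**Slope caveat.** The maximum centered-difference slope of the S1-S2
DI-APD curve is 1.15 when computed literally over all captured beats,
against 0.85 published. The excess comes entirely from the two points
adjacent to the capture boundary, where 5 ms coupling-interval steps
compress to <1 ms steps in mid-cable DI (conduction latency grows as S2
approaches refractoriness) and the premature beat's APD sits ~2.5 ms off
the steady-state restitution function; a ratio of two such shrinking
differences is not a robust slope estimate. Away from that boundary the
S1-S2 slope stays below 0.9, and the dynamic-protocol slope — the same
curve in this memory-free model — is 0.835. Both are reported.

**Spiral initiation (2D).** Cross-field S1-S2 on the 10×10 cm sheet: S1
(2 ms, 2× threshold) over the full left edge produces a planar wave; S2
(2 ms, 3× threshold) covers the lower-half rectangle — 80% of the
x-extent by ly/2 — delivered in the refractory tail of S1. The part of
the rectangle left of the S1 recovery boundary is excited, the part
beyond it blocks, and the broken front pivots around the recovery
boundary into a single spiral. S2 timing is found automatically: the
run advances until a 2 mm-wide mid-sheet monitor strip repolarizes
below −74.5 mV, then trial S2s from saved state locate the vulnerable
window — local capture with distal block, judged by probes 4 mm either
side of mid-sheet within a 30 ms horizon — by a 5 ms scan plus 1 ms
refinement; delivery at the window midpoint. The window is only a few
ms wide because recovery-variable refractoriness outlasts voltage
repolarization; a fully blocked or fully captured outcome raises a
diagnostic suggesting a rescan.

The rectangle's orientation matters. A thin strip parallel to the S1
front (the most literal reading of a "rectangle parallel to the wave
front over 80% of the edge") fails reproducibly at every delay in the
vulnerable window and at both tested resolutions: the S2 wave wraps
over the strip's free end and then rides the rightward-moving recovery
boundary, re-exciting the whole sheet within ~200 ms — the refractory
obstacle spans only ~70 ms of recovery spread, far less than half a
rotation period, so no phase gradient survives and all activity
annihilates by ~0.5 s. The perpendicular lower-half rectangle is the
classic cross-field geometry of the protocol literature and yields the
stable rotor the model is known for; it is the default here.

**Reentry analysis.** Per-node activation times are interpolated upward
−72.5 mV crossings recorded between 2 s and 4 s after S2; periods are
successive differences per node, the dominant period is the modal 1 ms
bin (ties toward the longer period), and the mean-period and mean-APD
maps flag nodes with insufficient events as NaN. The tip tracker is the
zero-normal-velocity method: per snapshot pair, marching-squares
contours of V = −60 mV and of the finite-difference dV/dt = 0 field are
intersected (exact segment intersections via computational-geometry
predicates), keeping at most one tip per frame by nearest-to-previous
continuity. The pseudo-electrogram treats −∇V as a dipole source density
in an infinite homogeneous volume conductor: a discrete sum of
−∇V·r/|r|³ over cells (centered-difference gradients) for an electrode
0.1 mm above the sheet center, reported in mV/mm; the lumped
conductivity ratio β is unknown in principle, so only the trace's shape
and periodicity are meaningful, not its scale.

At coarse preview resolution (dx = 0.5 mm) the blended operator
over-speeds the front and the wavelength exceeds the sheet, so the first
rotation self-terminates; reentry results are only meaningful at the
default resolution.

## Problem sizes and determinism

Everything is desk-scale by construction: the cable protocols integrate
81 nodes (≈0.6 s wall per simulated second), the full restitution pair
runs in ~1 minute, and the 4.4 s reentry simulation on 401×401 nodes
dominates the budget at roughly 15 minutes on one core (including the
automatic S2-timing scan). There is no
randomness anywhere in the model or protocols — no RNG is consumed — so
reruns are bit-identical; the acceptance script accepts a seed purely
for interface uniformity.

## Known limitations

- No bidomain, anisotropy, fiber orientation or 3D; no Hodgkin-Huxley
  or Markov channel detail, and the three current components are not
  individually physiological (only their sum is).
- The printed notch depth and the literal S1-S2 boundary slope are not
  reproducible within 2% by any consistent non-FEM discretization at the
  default steps (see above); both are reported as computed.
- With the default parameter set the model does not produce alternans
  (restitution slope < 1 over the usable range), so alternans-dependent
  phenomena are out of reach without re-parameterization (larger e2).
- The electrotonic amplitude loss depends on the isolated-cell stimulus
  convention (124.6-133.2 mV cell amplitude between 1× and 2×
  threshold); the package uses 2 ms at 2× cell threshold for consistency
  with the tissue protocols.
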