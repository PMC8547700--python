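# epicard

A three-variable phenomenological model of **human ventricular epicardial
tissue**, with single-cell, 1D-cable and 2D-sheet monodomain solvers,
restitution protocols, spiral-wave (reentry) analysis and
pseudo-electrograms. It is aimed at computational cardiac
electrophysiologists who want tissue-scale simulations — restitution
curves, vulnerability, reentry dynamics — at a fraction of the cost of
biophysically detailed ionic models.

## The model

The membrane state is (V, u, w): potential (mV), recovery variable and
transient-outward gate. The total ionic current is a shaped sum of three
FitzHugh–Nagumo-style contributions,

```
I_ion = g(u) · k · (I_exc + I_rec + I_to)

I_exc = c1 (V−B)(a − (V−B)/A)(1 − (V−B)/A)     cubic excitation
I_rec = c2 u (V−B)                              recovery
I_to  = c3 w (V−B) s_u ,   s_u = ((u_M−u)/u_M)² transient outward (notch)
g(u)  = (γ0 + γ1 u)(1 − tanh α(u−θu))/2 + g0   shape factor
```

with gate dynamics `du/dt = k·e·((V−B)/A − u)` (two-rate switch: e1 on
the plateau branch, boosted to g·e1 during the upstroke; e2 during
recovery) and `dw/dt = k·g·ew0·((V−B)/A − (dw0/s_u)·w)`. Tissue coupling
is the monodomain equation `∂V/∂t − ∇·(D∇V) = −I_ion + I_ext`,
D = 1.171 cm²/s, no-flux boundaries. Rest is (−85 mV, 0, 0); the
excitation threshold is a·A + B = −60.7 mV. Full equations, parameter
table, numerics and design rationale: [docs/methods.md](docs/methods.md).

## Worked example

```
$ epicard cable
apd90_ms = 267.3
amplitude_mV = 125.1
upstroke_vmax_V_per_s = 203.5
notch_min_mV = 8.46
plateau_max_mV = 22.76
cv_cm_per_s = 68.45
stimulus_amplitude = 6.289e+04
```

This paces a 2 cm cable at 1 Hz for ten beats with 2 ms stimuli at twice
the diastolic threshold (the threshold is found by bisection — here
31 445 mV/s, hence the stimulus 62 890 mV/s) and reports the mid-cable
action potential of the last beat: duration at 90% repolarization
267.3 ms, amplitude 125.1 mV, fastest upstroke 203.5 V/s, phase-1 notch
dipping to 8.5 mV before a 22.8 mV plateau dome, conduction velocity
68.5 cm/s — the AP morphology and speed of human epicardium.

Other entry points (`epicard <cmd> --help` for options):

```
epicard cell                      # isolated-cell AP, trace + features CSV
epicard restitution s1s2          # premature-extrastimulus APD/CV restitution
epicard restitution dynamic       # steady-state restitution + endpoints
epicard spiral run / analyze      # 2D reentry, period map, tip path, EGM
epicard convergence               # CV vs (dx, dt) + 5% step-halving gate
epicard validate                  # recompute & score the published values
epicard run config.toml           # any of the above from a TOML config
```

Configuration schema: [docs/config_schema.md](docs/config_schema.md).
Library API mirrors the CLI (`epicard.integrate_cell`,
`epicard.simulate_cable`, `epicard.s1s2_restitution`,
`epicard.initiate_spiral`, ...).

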