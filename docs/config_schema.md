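# Run configuration schema

Run configurations are TOML files with five flat sections; every key is
optional unless marked required. Unknown sections or keys fail
validation with a message naming the offending field. `epicard run
config.toml` (or `epicard.config.run_from_config`) executes the named
protocol, writes its artifacts into `[output] dir`, and records the
fully resolved configuration in `provenance.json` there.

## `[model]`

Any of the 18 parameter keys, overriding the default epicardial set:
`k, c1, c2, c3, a, A, B, e10, e2, gamma0, gamma1, alpha, theta_u, g0,
u_M, ew0, dw0, D`. Alternatively `params_file = "params.txt"` (flat
`key = value` lines, same keys) loads a base set which inline keys then
override. Units: `k` in 1/s, `A`/`B` in mV, `D` in cm²/s, the rest
dimensionless.

## `[grid]`

| key | default | meaning |
|---|---|---|
| `kind` | `"cable"` | `"cable"` (1D) or `"sheet"` (2D) |
| `length` | `2.0` | cable length, cm |
| `lx`, `ly` | `10.0` | sheet extent, cm |
| `dx` | `0.025` | node spacing, cm (0.25 mm) |

## `[solver]`

| key | default | meaning |
|---|---|---|
| `scheme` | `"split"` | `"split"` (Strang: Heun reaction + Crank–Nicolson diffusion, unconditionally stable) or `"explicit"` (forward Euler, requires `dt <= dx²/(2·d·D)`) |
| `dt` | `1e-4` | time step, s (0.1 ms) |
| `mass_blend` | `0.125` | blended-mass operator weight (0 = lumped, 1/6 = consistent P1) |

## `[protocol]`

`kind` (required): one of `cell`, `cable`, `s1s2`, `dynamic`, `spiral`,
`convergence`. Kind-specific options:

| key | applies to | default | meaning |
|---|---|---|---|
| `t_end` | cell, cable | 0.6 / 0.5 | simulated time, s |
| `amplitude` | cell, cable | 2× diastolic threshold | stimulus strength, mV/s |
| `amplitude_factor` | cell, cable | 2.0 | multiple of the diastolic threshold |
| `pulse_duration` | cell | 2e-3 | stimulus duration, s |
| `s1_cl` | s1s2 | 1.0 | S1 cycle length, s |
| `n_s1` | s1s2 | 10 | conditioning beats |
| `s2_time` | spiral | auto-scan | S2 delivery time, s |
| `s2_fraction` | spiral | 0.8 | fraction of the x-extent covered by the S2 rectangle |
| `s2_height` | spiral | ly/2 | S2 rectangle height, cm |
| `t_after_s2` | spiral | 4.0 | simulated time after S2, s |
| `snapshot_cadence` | spiral | none | V-frame cadence for tip tracking, s |

## `[output]`

| key | default | meaning |
|---|---|---|
| `dir` | `epicard_out` | artifact directory (created if needed) |

## Example

```toml
[model]
e2 = 0.02

[grid]
kind = "cable"
length = 2.0

[solver]
scheme = "split"
dt = 1e-4

[protocol]
kind = "dynamic"

[output]
dir = "results/dynamic_e2_0.02"
```
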