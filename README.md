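# morphospheroid

A simulator library for morphoelastic tumour-spheroid growth. The spheroid
is an incompressible neo-Hookean solid growing under spherical symmetry,
with the deformation gradient split multiplicatively into a growth part
(isotropic growth stretch `gamma(R)`) and an elastic part. Growth is driven
by a quasistatic, diffusion-limited nutrient field and — in the
stress-coupled models — moderated by the solid stress that growth itself
generates.

Five growth laws of increasing refinement are implemented:

| Law | Growth rate (per unit `k`) | Necrosis |
| --- | --- | --- |
| `M1` | `c - c_hat` | decaying below threshold |
| `M2` | `n(sigma_r) (c - c_hat)` for perfused tissue | decaying |
| `M3` | as M2, rate clamped at zero | permanent (front `R_N`) |
| `M4` | `n(min over body of {sigma_r, sigma_theta}) (c - c_hat)` | permanent |
| `M5` | M4 times a local factor `n(beta sigma_r)` | permanent |

where `n` is a piecewise-linear stress modifier that shuts growth off below
a compressive threshold `sigma_hat <= 0`. The package also provides the
closed-form validators of the nutrient-only model (explicit outer-radius
solution, steady-state geometry, boundary-stress asymptotics), residual
stress profiles (zero surface traction), and multi-condition growth-curve
fitting with shared parameters.

All internal computation is dimensionless: lengths in units of the
diffusive lengthscale `L = sqrt(D c_inf / lam)`, times in units of
`T = 1 / (k c_inf)`, stresses in units of the shear modulus `mu`, and
concentrations in units of the surface value `c_inf`. Dimensional
parameter sets are converted at the package boundary.

## Library quick start

```python
import morphospheroid as ms

# canonical nutrient-only run: chat = 4/5, B = L
params = ms.DimensionlessParams(chat=0.8, B_over_L=1.0)
traj = ms.simulate(params, "M1", t_end=30.0, controls=ms.Controls(steady_tol=0.0))
print(traj.b[-1])                       # ~ sqrt(3), the analytic steady radius
print(ms.steady_state_radius(params))   # closed-form summary

# stress-arrested robust model with residual stress
p5 = ms.FIGURE_PARAMS["fig9"]
run = ms.simulate(p5, "M5", 2000.0, ms.Controls(steady_tol=1e-8, snapshot_stride=10**9))
profile = ms.residual_profiles(run.final_state, run.params)
print(profile.sigma_theta[-1] > 0)      # tensile residual hoop stress at the surface
```

`ms.FIGURE_PARAMS` ships the named parameter fixtures used throughout
(`fig3`, `fig5_text`, `fig5_caption`, `fig6`, `fig7`, `fig9`).

## Command line

```sh
morphospheroid simulate --law M1 --fixture fig3 --t-end 30 --out runs/fig3
morphospheroid steady-state --fixture fig3
morphospheroid residual-stress --law M5 --fixture fig9 --t-end 100 --out fig9_residual.csv
morphospheroid synth --law M5 --config synth.yaml --seed 1 --out data/
morphospheroid fit --law M5 --data data/*.csv --config fit.yaml --seed 1 --out fitout/
```

`simulate` writes a growth-curve CSV (`t`, `b`, centre radial stress,
necrotic radius, global stress measure, in units of `T`, `L`, `mu`) plus a
JSON run manifest; with `--snapshot-stride` it also writes per-snapshot
state and stress CSVs. Parameter files are flat YAML/JSON key-value
mappings using either the dimensionless vocabulary (`chat`, `kappa_mu`,
`sigmahat_mu`, `beta`, `B_over_L`) or the dimensional one (`k`, `c_inf`,
`c_hat`, `lam`, `D`, `mu`, `kappa`, `sigma_hat`, `beta`, `B`).

## Fitting

`fit` minimises the summed squared radius residuals over one or more
growth curves, sharing all biology/mechanics parameters across conditions
and freeing only the initial radius `B` and the external stiffness
`kappa_mu` per dataset; free-suspension datasets pin `kappa_mu = 0`.
Optimisation is bounded Nelder-Mead from Latin-hypercube multistarts and
is deterministic per seed. `synthesize_growth_data` / `synth` generate
model-based multi-condition curves with additive Gaussian noise for
parameter-recovery experiments.

## Numerical notes

- Time integration is classical RK4 on `ln gamma` with a fixed step
  (default `T/200`); radii, nutrient, and stress are quasistatic closures
  recomputed at every stage. Radii come from trapezoid quadrature of
  `gamma^3 d(R^3)`; radial stress from inward trapezoid quadrature with
  the removable centre singularity evaluated as zero.
- Material turnover squeezes the proliferating rim into an exponentially
  thin Lagrangian layer. Interior grid nodes are therefore redistributed
  uniformly in the current Eulerian radius whenever spacing degrades
  (`Controls(remesh=...)`); without this the outer-radius error grows
  exponentially once the layer falls below the grid spacing.
- Under the unbounded-growth laws (M1/M2) the layer width shrinks like
  `exp(-3 k (c_inf - c_hat) t)` and falls below double-precision
  resolution near `k (c_inf - c_hat) t ~ 10`; keep horizons inside that
  or rely on the closed-form results. Runs that exceed the growth-stretch
  guard terminate cleanly with status `unbounded_growth_stretch`.
- The parabolic nutrient profile is extrapolated (with a logged warning
  and a validity flag, or an exception in strict mode) when the outer
  radius exceeds the depletion radius `sqrt(6) L`.
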