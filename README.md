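# fsgsim

Fluid-solid-growth (FSG) simulation of intracranial aneurysm stability,
enlargement and restabilization on idealized geometries.

Most detected intracranial aneurysms (IAs) are stable; deciding which
ones will enlarge is the clinical question.  FSG models couple the slow
biology of the wall — collagen turnover, mass loss, homeostatic
adaptation — to the hemodynamic stimuli that drive it.  `fsgsim`
implements such a model at desk scale, for researchers in vascular
mechanobiology who want a tested, scriptable reference implementation of
the constitutive and growth-and-remodelling (G&R) laws without a cluster
CFD/FEM stack:

* **Collagen recruitment-distribution mechanics.**  Each wall layer
  (media, adventitia) is a nearly incompressible neo-Hookean matrix
  reinforced by collagen fiber families whose waviness follows a
  triangular distribution of recruitment stretches λ̄₄ᵣ ~ (min, mode,
  max).  Individual fibers are linear in the 1st Piola–Kirchhoff sense,
  so the ensemble stress ∂Ψ/∂Ī₄ has closed-form toe/affine branches,
  validated against quadrature to 1e-8.
* **Pulsatile flow metrics.**  The wall shear stress (WSS) vector
  τ = ση − ((ση)·η)η, its principal tangent directions over a cardiac
  cycle, and the WSS aspect ratio (WSSAR) — 0 for uni-directional, 1 for
  fully bi-directional flow — with the two quadratic degradation
  stimuli F_WSS (low WSS) and F_AR (high WSSAR).
* **Growth and remodelling.**  Mass degradation ∂m/∂t = −F·D_max·m,
  recruitment remodelling toward the attachment-stretch distribution at
  rate α₀, fibroblast-driven collagen growth, and attachment-stretch
  adaptation (the stabilization mechanism), integrated explicitly at
  dt = 0.02 yr.
* **Idealized mechanics.**  A two-layer axisymmetric parent + neck +
  dome membrane with through-thickness integration replaces the FEM
  solver; a Poiseuille-based surrogate with geometric feedback (or your
  own CSV/VTK WSS series) replaces the CFD solver.

See `docs/methods.md` for the model, assumptions, parameter defaults and
limitations.

## Worked example

The default configuration is a stable 8 mm dome on a 4 mm-diameter
parent vessel with the reference physiological parameter tables.

```python
import warnings; warnings.simplefilter("ignore")
from fsgsim import (RunConfig, initialize_state, run_homeostasis,
                    run_evolution, summarize_trajectory)

cfg = RunConfig()
state, waveform = initialize_state(cfg)

homeo = run_homeostasis(state, waveform, cfg)
print(f"homeostasis: converged in {homeo.iterations} iterations")

dome = state.geometry.region == "dome"
modal = state.max_fiber_stats()[dome, 1, :, 1]
print(f"dome adventitia modal fiber stretch: {modal.mean():.4f}")

traj = run_evolution(state, waveform, cfg, scenario="low_wss")
df = summarize_trajectory(traj)
print(f"apex radius: {1e3*df.apex_radius.iloc[0]:.3f} -> {1e3*df.apex_radius.iloc[-1]:.3f} mm")
print(f"minimum collagen mass: {df.min_m_c.iloc[-1]:.3f}")
print(f"max |J-1| over the run: {100*df.max_jacobian_dev.max():.3f}%")
print(f"final remodelling-rate norm: {df.max_remodelling_rate.iloc[-1]:.2e} /yr")
```

prints

```
homeostasis: converged in 27 iterations
dome adventitia modal fiber stretch: 1.0498
apex radius: 4.405 -> 4.742 mm
minimum collagen mass: 0.771
max |J-1| over the run: 0.102%
final remodelling-rate norm: 2.22e-15 /yr
```

Reading: the fixed-point search finds the spatially heterogeneous
recruitment field that puts the loaded collagen fabric at its
homeostatic (attachment) stretch distribution — the load-bearing dome
adventitia sits at its modal target 1.05.  Two years of low-WSS-driven
degradation then shrink the sac's constituent masses (collagen down to
0.77 of reference at the apex) and enlarge it, the low-WSS region
deepening with it; one year of attachment adaptation restabilizes the
enlarged sac, driving every remodelling rate to numerical zero with an
elevated, spatially variable attachment field.  Throughout,
near-incompressibility holds to 0.1%.

The same pipeline is scriptable from the shell:

```sh
fsgsim homeostasis --out state.h5
fsgsim evolve --state state.h5 --scenario low_wss --out run/
fsgsim fixtures --out fx/            # canonical synthetic WSS rosettes
fsgsim metrics --wss fx/rosettes.csv --out metrics.csv
fsgsim report --state run/final_state.h5
```

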