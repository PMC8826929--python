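# gibeta

Modelling how the β-cell's own insulin receptor shapes glucose
homeostasis.  `gibeta` implements a glucose–insulin–β-cell ODE system —
a Topp-type model extended with an autocrine negative feedback of
insulin on insulin secretion — together with the estimation machinery
built on it:

- **Model core** — the GIβ system

      dG/dt = R0 − (EG0 + S_P·I)·G
      dI/dt = β·σ0/(1 + Sβ·I) · G²/(α + G²) − k·I
      dβ/dt = (−d0 + r1·G − r2·G²)·β

  with closed-form/bracketed steady-state solvers, a stiff-capable
  integrator, and a fast two-equation reduction (β frozen) for
  glucose-tolerance-test timescales.  Sβ = 0 removes the feedback and
  recovers the classical Topp model exactly.
- **Clamp analysis** — a parameter-free steady-state estimator of the
  β-cell insulin sensitivity Sβ (nM⁻¹) from hyperglycemic-clamp insulin
  in control vs β-cell insulin-receptor-knockout groups:
  Sβ = (I_m − I_wt)/I_wt² (derivation variant) or (I_m − I_wt)/I_m²
  (printed variant), with SEM and tests against zero.
- **GTT analysis** — in-silico glucose tolerance tests (+20 mM bolus
  from steady state), AUGC/AUIC surfaces over (Sβ, S_P), and inversion
  of experimental AUGC bands into peripheral-insulin-sensitivity (S_P)
  intervals by band intersection.
- **Calcium traces** — the oscillation-counting rule for Fura-2
  ratio traces (local maxima exceeding the 3 mM-baseline median by
  >20% during stimulation) plus per-trace features.
- **Synthetic data** — deterministic generators for all of the above
  with embedded ground truth, so every estimator is scored against
  known answers.

Intended users: quantitative physiologists and modellers studying islet
biology who want a tested, reproducible reference implementation of
these analyses.  See `docs/methods.md` for model details, parameter
units and defaults, and known statistical limitations.

## Worked example

```python
import numpy as np
from gibeta import default_params, steady_state_full, clamp_steady_insulin
from gibeta.synth import ClampConfig, gen_clamp_dataset
from gibeta.clamp import estimate_sbeta

p = default_params()                     # wildtype-female defaults, Sβ = 3.4 nM⁻¹
G, I, beta = steady_state_full(p)
print(G, I, beta)                        # 8.0 mM, 0.149 nM, 0.992

# steady clamp insulin at the 19 mM target, with and without feedback
print(clamp_steady_insulin(p, 19.0, beta))                     # 0.219 nM
print(clamp_steady_insulin(p.replace(Sbeta=0.0), 19.0, beta))  # 0.382 nM

# recover Sβ from a synthetic clamp cohort (14 animals, 10% noise)
ds = gen_clamp_dataset(ClampConfig(seed=0))
est = estimate_sbeta(ds.control, ds.knockout, variant="derivation")
print(f"{est.mean:.3f} ± {est.sem:.3f} nM⁻¹ (p={est.p_vs_zero:.1e})")
# 3.314 ± 0.065 nM⁻¹ (p=2.1e-14)
```

The knockout steady-state insulin exceeds the control value (0.382 vs
0.219 nM): removing the autocrine brake produces the
hyperinsulinemia that the estimator inverts — here recovering the
generating Sβ = 3.4 nM⁻¹ within its uncertainty.

## Analysis scripts

Numbered drivers under `analysis/` run the pipeline stages end to end
and write tables to `results/`:

```sh
python analysis/01_simulate_feedback_gtts.py        # GTT scan across Sβ
python analysis/02_estimate_sbeta_from_clamps.py    # Sβ from synthetic clamps
python analysis/03_augc_surface_and_sp_inversion.py # AUGC surface + S_P intervals
python analysis/04_count_calcium_oscillations.py    # calcium peak counts
```

A thin CLI exposes the same operations
(`gibeta gen-synthetic | fit-sbeta | simulate-gtt | augc-surface |
estimate-sp | count-peaks`); every run writes a provenance JSON next to
its outputs.

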