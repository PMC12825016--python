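# nanopbpk

Minimal physiologically based pharmacokinetic (mPBPK) modelling of silica
nanoparticle (SiNP) biodistribution in mice and humans.

Engineered silica nanoparticles — mesoporous or non-porous spheres and
rods, bare or aminated — distribute through the body in ways that depend
strongly on their size, shape, porosity and surface charge. After an
intravenous bolus they are carried to organs by blood flow, partly retained
by tissue binding and macrophage uptake, and eliminated through the kidneys
(urine) and the mononuclear phagocyte system, MPS = liver + spleen (feces).
`nanopbpk` implements a seven-compartment linear mPBPK model of this
process together with everything needed to use it as an analysis pipeline:
parameter calibration from biodistribution data, mouse→human allometric
scaling, global sensitivity analysis, non-compartmental analysis (NCA) and
a synthetic-data generator that mirrors the layout of a typical
radiotracer biodistribution study.

## The model

States: concentrations C_p, C_lu, C_mps, C_k, C_o in plasma, lungs, MPS,
kidneys and the lumped remaining tissue ("others"), plus cumulative
excreted masses M_u (urine) and M_f (feces). Transport is
perfusion-limited; organ *i* exchanges with plasma through its blood flow
Q_i, and only the unbound fraction f_i of particles in the organ can
return to circulation. The bound pool (1 − f_i)·C_i is eliminated in the
two excreting organs with first-order rate constants k_e,mps and k_e,k:

    V_p  dC_p/dt   = Σ_i Q_i f_i C_i − (Q_lu + Q_mps + Q_k + Q_o) C_p
    V_i  dC_i/dt   = Q_i C_p − Q_i f_i C_i                    (i = lu, o)
    V_mps dC_mps/dt = Q_mps C_p − Q_mps f_mps C_mps − (1−f_mps) k_e,mps V_mps C_mps
    V_k  dC_k/dt   = Q_k C_p − Q_k f_k C_k − (1−f_k) k_e,k V_k C_k
    dM_u/dt = (1−f_k) k_e,k V_k C_k ;   dM_f/dt = (1−f_mps) k_e,mps V_mps C_mps

with C_p(0) = D/V_p (the full dose in plasma) and all else zero. Total
mass V_p C_p + Σ V_i C_i + M_u + M_f is conserved exactly. Volumes and
the lung/kidney flows are physiological constants; the eight
nanoparticle-specific quantities (f_lu, f_mps, f_k, f_o, k_e,mps, k_e,k,
Q_mps, Q_o) are estimated from data. Packaged parameter tables cover
mouse and human physiology and seven fitted nanoparticle sets
(8A, AR8, MA, Meso, SA, Stöber in mice; C dots in humans).

## Worked example

```python
import numpy as np
from nanopbpk import (
    DoseSpec, MinimalPBPKModel, StudyDesign,
    generate_dataset, load_parameter_tables,
)

phys, kin = load_parameter_tables("mouse", "Meso")
dose = DoseSpec.from_per_bw(20.0, phys.bw)          # 20 mg/kg -> 400 µg

# synthetic study: 5 tissue harvests + 4 excreta collections, n = 5, 5% CV
data = generate_dataset(phys, kin, dose, StudyDesign(cv=0.05, seed=1))

model = MinimalPBPKModel(data, phys, log_residuals=True)
results = model.fit(n_starts=8, seed=1)
print(results.summary())
```

prints (abridged):

```
        Minimal PBPK fit: Meso (mouse)
=============================================
parameter estimate std err  ci 2.5%  ci 97.5%
---------------------------------------------
     f_lu  0.00599 4.92e-05 0.005888 0.006091
    f_mps 0.004825 0.000143 0.004532 0.005119
      f_k   0.5155  0.00543   0.5043   0.5267
      f_o   0.0642  0.00243  0.05918  0.06921
  k_e_mps 0.009912 0.000108  0.00969  0.01013
    k_e_k    3.403   0.0655    3.268    3.538
    q_mps    3.059   0.0311    2.995    3.123
      q_o    1.659   0.0178    1.623    1.696
---------------------------------------------

objective (0.5*SSR): 0.00372726   n_obs: 33
overall Pearson R: 0.9996
per-compartment R: plasma=1.000, lungs=0.999, mps=1.000, kidneys=1.000, others=1.000, urine=0.999, feces=1.000
multistart seed: 1; attempts: 9
```

The estimates recover the generating Meso parameter set (f_k = 0.513,
k_e,k = 3.41 h⁻¹, …) to within a few percent at 5% measurement noise, and
the overall Pearson correlation between model and observations is ≈ 1.
`results.confidence_band(times)` gives pointwise 95% bands around the
fitted trajectories, and `nanopbpk.scaling.build_human_model` turns a
mouse fit into the initial guess for a human recalibration
(k_e scaled by (70/0.02)^−0.25 ≈ 0.13).

A command-line interface exposes the same stages:

```bash
nanopbpk --seed 1 --outdir out simulate --np-label Meso
nanopbpk --seed 1 --outdir out gsa --np-label Meso
nanopbpk --seed 1 --outdir out nca --profile out/profile.csv --dose-ug 400
```

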