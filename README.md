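# gamdkit

Gaussian-accelerated molecular dynamics (GaMD) boost construction,
cumulant-expansion free-energy reweighting, ligand-pose clustering and
salt-bridge structure analysis — exercised on analytically tractable toy
receptor systems.

## The problem

GaMD is an enhanced-sampling method: whenever the system potential V falls
below a threshold E, a harmonic boost

    ΔV = ½ k (E − V)²,  V < E

is added, flattening barriers while keeping the boost distribution narrow
and near-Gaussian.  The threshold and force constant are chosen from running
potential statistics (V_min, V_max, V_avg, σ_V):

    V_max ≤ E ≤ V_min + 1/k,    k = k0 / (V_max − V_min),  0 < k0 ≤ 1
    lower bound (E = V_max):  k0 = min(1, (σ0/σ_V)·(V_max−V_min)/(V_max−V_avg))
    upper bound (E = V_min + 1/k):  k0″ = (1 − σ0/σ_V)·(V_max−V_min)/(V_max−V_avg),
                                    accepted iff 0 < k0″ ≤ 1, else the lower rule

with σ0 the user ceiling on σ_ΔV.  Canonical potentials of mean force are
recovered per histogram bin j through the cumulant expansion to second order

    p(A_j) ∝ p*(A_j)·exp(β C1 + β² C2 / 2),   C1 = ⟨ΔV⟩_j,  C2 = Var(ΔV)_j
    F(A) = −k_B T ln p(A), min-shifted to 0,

which is exact when the per-bin boost is Gaussian.  Around this core the
package provides sieved DBSCAN clustering of ligand poses with reweighted
cluster free energies, and coordinate-file analysis (atom-pair distances,
Kabsch-superposition RMSD, contact residues, three-state salt-bridge
classification) of the kind used to characterize positive allosteric
modulation of a G-protein-coupled receptor, where a modulator bound at an
extracellular-loop site biases a glutamate–lysine salt bridge toward its
closed state and thereby stabilizes agonist binding.

Because all-atom receptor simulation is far beyond desk scale, the package
ships a synthetic "allosteric toy receptor" — agonist (2D), modulator (2D)
and a salt-bridge coordinate, with explicit coupling constants — plus exact
Boltzmann-quadrature oracles, so every stage of the analysis can be checked
against ground truth.  It is a library for people studying or teaching
enhanced-sampling reweighting, and a reference implementation of the boost
algebra; it is not an MD engine for real force fields.

## Worked example

```python
import numpy as np
import gamdkit as gk
from gamdkit.potentials import exact_pmf

dw = gk.make_double_well(barrier_height=6.0, well_separation=2.0, asymmetry=1.0)
cfg = gk.SimulationConfig(n_steps_cmd=2000, n_steps_equil=15000,
                          n_steps_production=300_000, save_stride=5, seed=0)
prod = gk.run_gamd(dw, cfg)["production"]
pmf = gk.reweight(prod.coords[:, 0], prod.dv_total,
                  np.linspace(-2, 2, 45), min_count=10)
```

Running `python examples/01_double_well_reweighting.py` (the same
computation) prints:

```
boost parameters: E = 9.49, k0 = 1.00 (lower bound)
boost potential:  dV = 3.02 ± 1.17 kT over 60000 frames
recovered well asymmetry: 0.80 kT (built: 1.00 kT)
max |reweighted - exact| over sampled bins: 0.26 kT
```

The threshold was set to the lower bound (E at the largest observed
potential), the mean boost is ~3 k_B T, and reweighting recovers the
constructed 1 k_B T well asymmetry to 0.2 k_B T, with the whole profile
within 0.26 k_B T of the exact Boltzmann-quadrature result.

The other examples cover the two-arm allosteric experiment
(`02_allosteric_experiment.py`), sieved pose clustering with reweighted
cluster free energies (`03_pose_clustering.py`), and salt-bridge geometry
from PDB files (`04_salt_bridge_structures.py`).  Each prints the numbers it
computes and a line on what they mean.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch: the salt-bridge distances and state labels of the
reference geometries, the double-well reweighting benchmark against the
exact oracle, and the full two-arm, five-seed allosteric experiment with its
occupancy-conditioned variance/cluster/closed-fraction comparisons, then
writes the JSON report to `--out`.  It takes a couple of minutes on one CPU.

## Layout

| module                 | contents |
| ---------------------- | -------- |
| `gamdkit.potentials`   | toy potentials, allosteric toy system, Boltzmann oracles |
| `gamdkit.engine`       | BAOAB Langevin + boost statistics/parameters/phases |
| `gamdkit.reweighting`  | cumulant-expansion PMFs, anharmonicity diagnostic |
| `gamdkit.clustering`   | sieved DBSCAN, cluster free energies, site occupancy |
| `gamdkit.structure`    | PDB I/O, distances, RMSD, contacts, state classification |
| `gamdkit.pipeline`     | config-driven experiment orchestration |

See `docs/methods.md` for the model, parameter choices and limitations.
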