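"""Boosted sampling of a double well and recovery of its exact free-energy
profile by cumulant reweighting.

Builds a 6 kT, asymmetry-1 double well, runs conventional-MD statistics
collection, boost equilibration and production, then reweights the sampled
histogram and compares it with the exact Boltzmann-quadrature profile.
"""

import numpy as np

import gamdkit as gk
from gamdkit.potentials import exact_pmf

potential = gk.make_double_well(barrier_height=6.0, well_separation=2.0,
                                asymmetry=1.0)
config = gk.SimulationConfig(
    n_steps_cmd=2000, n_steps_equil=15000, n_steps_production=300_000,
    save_stride=5, seed=0)
result = gk.run_gamd(potential, config)
prod = result["production"]
params = prod.final_params["total"]

print(f"boost parameters: E = {params.E:.2f}, k0 = {params.k0:.2f} "
      f"({params.effective_bound} bound)")
print(f"boost potential:  dV = {prod.dv_total.mean():.2f} ± "
      f"{prod.dv_total.std():.2f} kT over {prod.n_frames} frames")

edges = np.linspace(-2.0, 2.0, 45)
pmf = gk.reweight(prod.coords[:, 0], prod.dv_total, edges, min_count=10)
oracle = exact_pmf(potential, edges)

centers = pmf.centers(0)
left = np.nanmin(pmf.free_energy[centers < 0])
right = np.nanmin(pmf.free_energy[centers > 0])
deviation = np.abs(pmf.free_energy[pmf.mask]
                   - oracle.free_energy[pmf.mask]).max()
print(f"recovered well asymmetry: {left - right:.2f} kT (built: 1.00 kT)")
print(f"max |reweighted - exact| over sampled bins: {deviation:.2f} kT")
# The asymmetry estimate shows the reweighting undoing the boost's tilt of
# the populations; the deviation line bounds the whole-profile error in kT.
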