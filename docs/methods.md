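# Methods

## Boost potential and parameter selection

The engine integrates Langevin dynamics (BAOAB splitting, unit masses, fixed
timestep, explicit integer seed; one force evaluation and one Gaussian
vector per step, so runs are bitwise reproducible).  The GaMD boost

ΔV(r) = ½ k (E − V(r))² for V < E, else 0

is applied on top of the unbiased force as a scale factor (1 − k(E − V)) on
∇V; the scale lies in [0, 1] whenever E respects its admissible range
V_max ≤ E ≤ V_min + 1/k.  Writing k = k0/(V_max − V_min), the effective
force constant k0 is chosen from running potential statistics by the
lower-bound rule (E = V_max) with k0 clamped to 1, or by the upper-bound
rule (E = V_min + 1/k) with automatic fallback to the lower rule when its
k0″ leaves (0, 1].  The default threshold placement is the lower bound.

Runs proceed cmd → equilibration → production.  The conventional (cmd)
phase only collects statistics; during equilibration the boost is active and
E/k0 are refreshed from the running statistics every `refresh_stride`
(default 1000) steps, the statistics window extending back to the cmd start;
at production start the parameters are frozen and ΔV is recorded per saved
frame.  Statistics-update schemes differ between production MD codes; the
scheme above is this package's single documented convention.  Dual boost
maintains independent statistics and parameters for a named component (the
"dihedral-analog"; for the toy receptor, the salt-bridge term) and for the
total potential; the recorded ΔV is the sum.

Units are reduced throughout: k_B T = 1 at the reference temperature,
lengths in arbitrary "Å-analog" units, timestep 0.01, friction 1.

### σ0 and system size

σ0, the ceiling on the boost standard deviation, defaults to 6 k_B T at the
API level.  For all-atom systems σ_V is large (tens of k_B T), so a σ0 of a
few k_B T enforces a genuinely narrow, perturbative boost with k0 well below
1.  A few-degree-of-freedom toy instead has σ_V of order 1 k_B T; a σ0 of
several k_B T then disables the narrowing principle entirely (k0 clamps
to 1) and the boost erases the free-energy differences near the bottom of
the landscape — the biased trajectory loses its basin preferences.  The
default experiment therefore sets σ0 = 0.5 k_B T, reproducing the
σ0/σ_V ≈ 0.1–0.2 ratio of standard practice (measured k0 ≈ 0.33 for the
total-potential boost, 0.66 for the salt-bridge component).  When adapting
the pipeline to other toy systems, scale σ0 with the measured σ_V rather
than treating it as an absolute constant.

### Boost Gaussianity

The `anharmonicity` diagnostic is the entropy deficit
γ = ½ ln(2πe σ̂²) − Ŝ ≥ 0 (nats), with Ŝ a histogram estimate of the boost
sample's differential entropy; Gaussian samples give γ ≈ 0, and γ < 0.1 is
taken as "near-Gaussian" (a zero-variance sample returns 0 by convention).
On multi-term systems (the allosteric toy under dual boost) the production
boost passes this screen (γ ≈ 0.09).  On a single-coordinate toy it does
not (γ ≈ 0.45 for the double-well benchmark): with one degree of freedom
there is no central-limit averaging and the global ΔV distribution is
intrinsically skewed.  Reweighting accuracy is nevertheless excellent there,
because what the cumulant truncation needs is small *per-bin* ΔV variance —
and conditioned on the collective variable, ΔV of a 1D system is nearly
deterministic.  The global diagnostic is a screen for the multi-dimensional
case, not a validity condition for 1D toys.

## Reweighting

Per bin j with at least `min_count` (default 10) frames, C1 is the mean and
C2 the population variance of ΔV; the reweighted probability is
p(A_j) ∝ p*(A_j) exp(βC1 + β²C2/2), normalized over unmasked bins, and
F = −k_B T ln p min-shifted to zero.  Bins below the count threshold are
masked (NaN free energy), never extrapolated.  The expansion is truncated
at second order — exact for Gaussian per-bin boosts — with no
exponential-average fallback.  Frames falling outside the binning grid are
dropped.  Probabilities are per-bin masses; with equal bin widths this
differs from a density convention only by the additive constant that
min-shifting removes.  2D surfaces use the same machinery on a product grid;
the plotting helper caps the display at 8 k_B T.

## Toy allosteric receptor

Coordinates: agonist a ∈ R² in an orthosteric well system, modulator
(PAM) p ∈ R² with a single allosteric site well, and a 1D salt-bridge
coordinate s with a triple well (minima at 3.0 / 7.1 / 14.8, echoing the
closed / intermediate / open distances of the real extracellular bridge;
the numbers are presentational — units are reduced).  Soft polynomial walls
confine each coordinate.  Two couplings create the allosteric chain:

* c1 (default 4 k_B T): a smooth Gaussian occupancy of the PAM at its site
  deepens the closed salt-bridge well — modulator binding biases the bridge
  closed;
* c2 (default 0.8): a Gaussian bump of s on the closed state multiplies the
  orthosteric well depth by (1 + c2) — a closed bridge holds the agonist
  more tightly.

With c1 = c2 = 0 the energy separates and the three coordinates are
independent under the Boltzmann distribution (tested both directly on the
energy terms and by a chi-square contingency test on sampled, fast-mixing
variants).  The couplings are free parameters of the emulation — no
quantitative coupling is available to fit — chosen a priori as few-k_B T
allosteric energies.

Two equilibrium requirements fix the remaining defaults, both verified by
exact quadrature of the Boltzmann integrals (the oracles in
`gamdkit.potentials`), not by simulation outcomes:

* the *free* receptor samples all three bridge states.  Thermodynamic
  back-action is unavoidable: if a closed bridge stabilizes the agonist,
  a bound agonist stabilizes the closed bridge.  The base closed-well depth
  (0.5 k_B T) therefore absorbs the ≈ 2.7 k_B T the c2-coupling adds,
  giving closed/intermediate/open weights of 0.38/0.26/0.36 without PAM;
* the PAM *binds and stays bound*: site well depth 6 k_B T makes the bound
  dwell time long compared to salt-bridge relaxation (occupancy-conditioned
  statistics are meaningless if the modulator exchanges faster than the
  bridge responds), while binding remains diffusion-limited and completes
  early in equilibration.  PAM-bound closed weight: 0.96.

Site occupancy for analysis is a hard indicator (distance to the site
center ≤ 1.5 length units); the energetic coupling uses a smooth Gaussian
of width 1.0.

## Pose clustering

DBSCAN (scikit-learn, Euclidean metric) runs on every `sieve_stride`-th
frame; each remaining frame joins the cluster of its nearest clustered
sieved frame if that distance is ≤ eps, and is otherwise noise — assigning
arbitrarily distant frames would break the density semantics, so the
distance guard is deliberate.  Ties go to the lowest cluster id; stride 1
reduces exactly to plain DBSCAN.  min_samples defaults to 4; cluster
representatives are medoids over the sieved members (bounding the pairwise
cost).  Cluster free energies treat each cluster as one histogram bin of
the cumulant-2 reweighting; clusters with fewer than two members get C2 = 0
and a `low_count` flag.

## Structure analysis

PDB parsing, writing and Kabsch superposition delegate to biotite.  First
model only; alternate locations resolve to the highest occupancy (ties to
the first-listed conformer); author residue numbering is preserved.
Selection conventions: glutamate Cδ = atom name `CD`, lysine Nζ = `NZ`;
contact searches treat non-hetero atoms as receptor, with an inclusive
distance boundary.  Salt-bridge states use the classification grid
closed ≤ 4.5 Å < intermediate < 10 Å ≤ open — this package's documented
grid, chosen to separate the exemplar distances 3.0 / 7.12 / 14.82 Å of the
three reference conformations.

The reference structures themselves are **synthetic stand-ins**
(`make_synthetic_salt_bridge_structure`): glutamate and lysine residues
with idealized internal geometry placed so the Cδ–Nζ distance equals the
published value exactly.  The experimental coordinate files cannot be
fetched in an offline environment, so tests against these stand-ins
validate the write → parse → select → measure → classify pipeline, not the
crystallographic coordinates; with network access the same functions apply
unchanged to the real files.

## What a green test establishes — and what it does not

The synthetic world has exact oracles, so the tests demonstrate that the
boost formulas, the reweighting estimator, the sieve/assignment logic and
the geometric routines are correct, and that the qualitative allosteric
signature (occupancy → closed bridge → confined agonist) emerges in sampled
data when the stated couplings hold.  The toy omits: atomistic force
fields, solvent and membrane, multi-atom ligands with orientational
degrees of freedom, the system-size regime where ΔV is Gaussian by the
central limit theorem, and any quantitative correspondence to measured
pharmacology.  Cluster *counts* are a noisy statistic even in the toy:
per-seed occupied-vs-unoccupied comparisons fluctuate, and the meaningful
comparison is the across-seed mean (asserted as such).

## Numerical choices

* Exact PMFs: midpoint-rule quadrature, 200 subdivisions per bin per
  dimension (1e−6-level symmetry, 1e−4-level agreement with closed forms).
* Welford single-pass mean/variance for potential statistics; population
  (not sample) variance for C2 — negligible at production frame counts.
* Double-well construction pins the minima at ±separation/2 analytically,
  so built asymmetries are exact; the barrier is measured from the mean of
  the two well energies.
* Degenerate inputs raise: V_max = V_min or V_max = V_avg or σ_V = 0 in
  parameter selection (the offending quantity is named), negative ΔV in
  reweighting, empty inputs everywhere.
* Default test/benchmark sizes are scaled to one CPU: the full suite runs
  in ~2 minutes; the barrier-crossing comparison uses 3×10⁵ production
  steps per seed (a ten-fold longer run gives the same ordering with wider
  margins).

## Known limitations

* No replica exchange, constraints, periodic boundaries or GPU paths; the
  integrator is BAOAB-only.
* The exponential-average and Maclaurin-series reweighting variants are
  deliberately absent; multi-run combination (weighted-histogram style) is
  out of scope.
* 2D PMFs on short runs can leave poorly sampled corners masked; increase
  production length or bin width rather than lowering `min_count`.
* The anharmonicity screen is informative only for multi-term systems (see
  above).
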