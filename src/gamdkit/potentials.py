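"""Analytic toy potentials, an allosteric receptor-ligand toy system and exact
Boltzmann oracles.

Everything here is in reduced units: energies in k_B T at the reference
temperature, lengths in arbitrary "Å-analog" units.  The toy systems exist to
exercise the boost/reweighting/clustering machinery on problems whose exact
canonical statistics can be computed by quadrature, so every generator is
paired with a brute-force Boltzmann oracle.

The allosteric toy mimics the mechanism by which a positive allosteric
modulator (PAM) bound at an extracellular-loop site biases an
extracellular salt bridge towards its closed state, which in turn stabilizes
agonist binding at the orthosteric site:

    PAM occupancy --(c1)--> salt-bridge closed --(c2)--> deeper/narrower
                                                          orthosteric well

With both couplings zero the three coordinates (agonist, PAM, salt bridge)
are statistically independent under the Boltzmann distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from gamdkit.pmf import PMF

__all__ = [
    "ToyPotential",
    "AllostericToySystem",
    "make_double_well",
    "make_harmonic",
    "make_allosteric_toy",
    "exact_pmf",
    "boltzmann_marginal_s",
    "boltzmann_mean_s",
    "boltzmann_agonist_stats",
    "boltzmann_joint_s_displacement",
]


# ---------------------------------------------------------------------------
# generic analytic potential
# ---------------------------------------------------------------------------

@dataclass
class ToyPotential:
    """An analytic potential with energy and gradient callables.

    ``energy`` maps a coordinate array of shape ``(dimensionality,)`` to a
    float (k_B T units); ``gradient`` returns the corresponding derivative
    vector.  ``components`` optionally decomposes the energy into named terms
    (used by the engine's component/dual boost); when absent the potential is
    a single term named ``"total"``.
    """

    dimensionality: int
    energy: Callable[[np.ndarray], float]
    gradient: Callable[[np.ndarray], np.ndarray]
    domain_bounds: tuple[tuple[float, float], ...]
    label: str = ""
    start: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)
    components: dict[str, tuple[Callable, Callable]] | None = None

    def __post_init__(self) -> None:
        self.domain_bounds = tuple((float(a), float(b)) for a, b in self.domain_bounds)
        if len(self.domain_bounds) != self.dimensionality:
            raise ValueError("one (lo, hi) bound per dimension required")
        if self.start is None:
            self.start = np.zeros(self.dimensionality)
        self.start = np.asarray(self.start, dtype=float)

    # engine-facing decomposition -------------------------------------
    @property
    def term_names(self) -> tuple[str, ...]:
        if self.components is None:
            return ("total",)
        return tuple(self.components)

    def energy_and_gradient_terms(self, x: np.ndarray):
        """Per-term energies and gradients at ``x`` (dicts keyed by term name)."""
        if self.components is None:
            return {"total": float(self.energy(x))}, {"total": np.asarray(self.gradient(x))}
        vs = {}
        gs = {}
        for name, (efn, gfn) in self.components.items():
            vs[name] = float(efn(x))
            gs[name] = np.asarray(gfn(x))
        return vs, gs


def make_harmonic(stiffness: float = 1.0, center: float = 0.0,
                  extent: float = 6.0) -> ToyPotential:
    """1D harmonic well V(x) = stiffness/2 · (x − center)², a closed-form
    reference for sampler and PMF checks."""
    if stiffness <= 0:
        raise ValueError("stiffness must be positive")
    k, c = float(stiffness), float(center)

    def energy(x):
        return 0.5 * k * float((x[0] - c)) ** 2

    def gradient(x):
        return np.array([k * (x[0] - c)])

    half = extent / math.sqrt(k)
    return ToyPotential(
        dimensionality=1,
        energy=energy,
        gradient=gradient,
        domain_bounds=((c - half, c + half),),
        label=f"harmonic(k={k})",
        start=np.array([c]),
        metadata={"stiffness": k, "center": c},
    )


def make_double_well(barrier_height: float, well_separation: float,
                     asymmetry: float = 0.0) -> ToyPotential:
    """1D quartic double well with pinned minima and exact asymmetry.

    The quartic is constructed from its derivative
    ``V'(x) = κ (x² − a²)(x − b)`` with ``a = well_separation / 2``, so the two
    minima sit exactly at ±a.  ``b`` and ``κ`` are solved such that

    * the energy difference between the two minima equals ``asymmetry``
      exactly (the +a well is the deeper one), and
    * the barrier top lies ``barrier_height`` above the mean of the two well
      energies (for a symmetric well: above both minima).

    The deeper well is shifted to zero energy.  Analytic well/barrier energies
    and minima locations are recorded in ``metadata``.
    """
    if barrier_height <= 0:
        raise ValueError("barrier_height must be positive")
    if well_separation <= 0:
        raise ValueError("well_separation must be positive")
    if asymmetry < 0:
        raise ValueError("asymmetry must be non-negative")
    h = float(barrier_height)
    a = float(well_separation) / 2.0
    asym = float(asymmetry)

    def b_of_kappa(kappa: float) -> float:
        return -3.0 * asym / (4.0 * kappa * a**3)

    def mean_barrier(kappa: float) -> float:
        b = b_of_kappa(kappa)
        return kappa * (-b**4 / 12.0 + a**2 * b**2 / 2.0 + a**4 / 4.0)

    kappa0 = 4.0 * h / a**4          # exact for the symmetric case
    if asym == 0.0:
        kappa, b = kappa0, 0.0
    else:
        lo, hi = kappa0 * 1e-3, kappa0 * 1e3
        kappa = brentq(lambda k: mean_barrier(k) - h, lo, hi, xtol=1e-14, rtol=1e-14)
        b = b_of_kappa(kappa)
        if abs(b) >= a:
            raise ValueError("asymmetry too large relative to barrier: no double well")

    def raw(x: float) -> float:
        return kappa * (x**4 / 4.0 - b * x**3 / 3.0 - a**2 * x**2 / 2.0 + a**2 * b * x)

    shift = -raw(a)  # +a is the deeper well; set it to zero

    def energy(x):
        return raw(float(x[0])) + shift

    def gradient(x):
        t = float(x[0])
        return np.array([kappa * (t * t - a * a) * (t - b)])

    lim = 2.5 * a
    meta = {
        "kappa": kappa,
        "barrier_x": b,
        "minima": (-a, a),
        "well_energies": {"-a": raw(-a) + shift, "+a": 0.0},
        "barrier_energy": raw(b) + shift,
        "barrier_height": h,
        "asymmetry": asym,
    }
    return ToyPotential(
        dimensionality=1,
        energy=energy,
        gradient=gradient,
        domain_bounds=((-lim, lim),),
        label=f"double_well(h={h}, sep={2 * a}, asym={asym})",
        start=np.array([a]),
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# allosteric toy system
# ---------------------------------------------------------------------------

_DEFAULT_CONFIG: dict = {
    "temperature": 1.0,
    "pam_present": True,
    # orthosteric (agonist) energetics: main Gaussian well + shallow
    # secondary pose wells + confining polynomial wall
    "orth_center": (0.0, 0.0),
    "orth_depth": 5.0,
    "orth_width": 0.7,
    "secondary_wells": [
        {"center": (2.2, 0.0), "depth": 3.0, "width": 0.5},
        {"center": (-1.5, 1.6), "depth": 2.5, "width": 0.5},
    ],
    "agonist_wall_radius": 3.5,
    "agonist_wall_strength": 2.0,
    # allosteric (PAM) energetics: single Gaussian site well + wall
    "allo_center": (2.0, 0.0),
    "allo_depth": 6.0,   # deep enough that PAM dwell >> salt-bridge relaxation
    "allo_width": 0.8,
    "pam_wall_radius": 3.0,
    "pam_wall_strength": 2.0,
    # salt-bridge coordinate: triple well (closed/intermediate/open) + wall
    "sb_minima": (3.0, 7.1, 14.8),
    "sb_widths": (1.0, 1.2, 1.5),
    "sb_depths": (0.5, 2.5, 2.8),  # base closed well shallow: the c2 back-action
    # of the bound agonist deepens it by ~2.7 kT so the free receptor samples
    # all three states
    "sb_domain": (0.0, 18.0),
    "sb_wall_strength": 3.0,
    # couplings
    "c1": 4.0,    # PAM occupancy deepens the closed salt-bridge well (k_B T)
    "c2": 0.8,    # closed salt bridge deepens the orthosteric well (fractional)
    "occupancy_coupling_width": 1.0,   # Gaussian width of the smooth occupancy
    "site_radius": 1.5,                # hard indicator radius for analysis
}


@dataclass
class AllostericToySystem:
    """Toy receptor with agonist (2D), optional PAM (2D) and a salt-bridge
    coordinate ``s`` (1D).

    Coordinate layout is ``[ax, ay, px, py, s]`` with the PAM present and
    ``[ax, ay, s]`` without.  The energy is a sum of three named terms

    * ``orth`` — orthosteric (agonist) well system; its main-well depth grows
      by a factor ``(1 + c2·g(s))`` where ``g`` is a Gaussian bump centred on
      the closed salt-bridge state,
    * ``allo`` — PAM site well (absent when ``pam_present`` is false),
    * ``sb``  — salt-bridge triple well whose closed well is deepened by
      ``c1`` times a smooth Gaussian occupancy of the PAM at the allosteric
      site.

    With ``c1 = c2 = 0`` the terms decouple and the Boltzmann distribution
    factorizes over the three coordinates.
    """

    config: dict

    def __post_init__(self) -> None:
        c = dict(_DEFAULT_CONFIG)
        c.update(self.config)
        self.config = c
        s1, s2, s3 = c["sb_minima"]
        if not (s1 < s2 < s3):
            raise ValueError("sb_minima must satisfy s_closed < s_intermediate < s_open")
        for key in ("orth_depth", "allo_depth"):
            if c[key] <= 0:
                raise ValueError(f"{key} must be positive")
        if any(d <= 0 for d in c["sb_depths"]):
            raise ValueError("sb_depths must be positive")
        if c["c1"] < 0 or c["c2"] < 0:
            raise ValueError("couplings must be non-negative")
        self.pam_present = bool(c["pam_present"])
        self.temperature = float(c["temperature"])

    # -- layout --------------------------------------------------------
    @property
    def dimensionality(self) -> int:
        return 5 if self.pam_present else 3

    @property
    def agonist_slice(self) -> slice:
        return slice(0, 2)

    @property
    def pam_slice(self) -> slice | None:
        return slice(2, 4) if self.pam_present else None

    @property
    def s_index(self) -> int:
        return 4 if self.pam_present else 2

    @property
    def term_names(self) -> tuple[str, ...]:
        return ("orth", "allo", "sb") if self.pam_present else ("orth", "sb")

    # -- raw term functions (broadcastable) ----------------------------
    def _g_closed(self, s):
        """Gaussian bump on the closed salt-bridge state (used by both couplings)."""
        c = self.config
        sc = c["sb_minima"][0]
        w = c["sb_widths"][0]
        return np.exp(-((s - sc) ** 2) / (2.0 * w * w))

    def _orth_energy(self, ax, ay, s):
        c = self.config
        cx, cy = c["orth_center"]
        dx, dy = ax - cx, ay - cy
        depth = c["orth_depth"] * (1.0 + c["c2"] * self._g_closed(s))
        w = c["orth_width"]
        u = -depth * np.exp(-(dx * dx + dy * dy) / (2.0 * w * w))
        for sw in c["secondary_wells"]:
            sx, sy = sw["center"]
            ww = sw["width"]
            u = u - sw["depth"] * np.exp(
                -((ax - sx) ** 2 + (ay - sy) ** 2) / (2.0 * ww * ww))
        L = c["agonist_wall_radius"]
        r2 = ax * ax + ay * ay
        u = u + c["agonist_wall_strength"] * (r2 / (L * L)) ** 4
        return u

    def _occ_smooth(self, px, py):
        c = self.config
        gx, gy = c["allo_center"]
        w = c["occupancy_coupling_width"]
        return np.exp(-((px - gx) ** 2 + (py - gy) ** 2) / (2.0 * w * w))

    def _allo_energy(self, px, py):
        c = self.config
        gx, gy = c["allo_center"]
        w = c["allo_width"]
        u = -c["allo_depth"] * np.exp(-((px - gx) ** 2 + (py - gy) ** 2) / (2.0 * w * w))
        L = c["pam_wall_radius"]
        r2 = px * px + py * py
        return u + c["pam_wall_strength"] * (r2 / (L * L)) ** 4

    def _sb_base_energy(self, s):
        c = self.config
        u = 0.0
        for sk, wk, dk in zip(c["sb_minima"], c["sb_widths"], c["sb_depths"]):
            u = u - dk * np.exp(-((s - sk) ** 2) / (2.0 * wk * wk))
        lo, hi = c["sb_domain"]
        mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
        return u + c["sb_wall_strength"] * ((s - mid) / half) ** 10

    def _sb_energy(self, s, px=None, py=None):
        u = self._sb_base_energy(s)
        if self.pam_present and self.config["c1"] > 0 and px is not None:
            u = u - self.config["c1"] * self._occ_smooth(px, py) * self._g_closed(s)
        return u

    # -- engine-facing API ---------------------------------------------
    def energy_and_gradient_terms(self, x: np.ndarray):
        """Per-term energies (floats) and gradients (full-dimension arrays)."""
        c = self.config
        if self.pam_present:
            ax, ay, px, py, s = (float(v) for v in x)
        else:
            ax, ay, s = (float(v) for v in x)
            px = py = None
        d = self.dimensionality
        si = self.s_index

        # --- orth term
        cx, cy = c["orth_center"]
        dx, dy = ax - cx, ay - cy
        w0 = c["orth_width"]
        g_s = float(self._g_closed(s))
        depth = c["orth_depth"] * (1.0 + c["c2"] * g_s)
        Ga = math.exp(-(dx * dx + dy * dy) / (2.0 * w0 * w0))
        v_orth = -depth * Ga
        g_orth = np.zeros(d)
        g_orth[0] = depth * Ga * dx / (w0 * w0)
        g_orth[1] = depth * Ga * dy / (w0 * w0)
        if c["c2"] > 0:
            sc, wc = c["sb_minima"][0], c["sb_widths"][0]
            # ∂/∂s of −d0(1+c2 g(s))·Ga
            g_orth[si] = c["orth_depth"] * c["c2"] * Ga * g_s * (s - sc) / (wc * wc)
        for sw in c["secondary_wells"]:
            sx, sy = sw["center"]
            ww = sw["width"]
            Gk = math.exp(-((ax - sx) ** 2 + (ay - sy) ** 2) / (2.0 * ww * ww))
            v_orth -= sw["depth"] * Gk
            g_orth[0] += sw["depth"] * Gk * (ax - sx) / (ww * ww)
            g_orth[1] += sw["depth"] * Gk * (ay - sy) / (ww * ww)
        La = c["agonist_wall_radius"]
        ra2 = ax * ax + ay * ay
        ka = c["agonist_wall_strength"] / La**8
        v_orth += ka * ra2**4
        g_orth[0] += ka * 8.0 * ra2**3 * ax
        g_orth[1] += ka * 8.0 * ra2**3 * ay

        # --- sb term
        v_sb = 0.0
        dvds = 0.0
        for sk, wk, dk in zip(c["sb_minima"], c["sb_widths"], c["sb_depths"]):
            Gk = math.exp(-((s - sk) ** 2) / (2.0 * wk * wk))
            v_sb -= dk * Gk
            dvds += dk * Gk * (s - sk) / (wk * wk)
        lo, hi = c["sb_domain"]
        mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
        t = (s - mid) / half
        v_sb += c["sb_wall_strength"] * t**10
        dvds += c["sb_wall_strength"] * 10.0 * t**9 / half
        g_sb = np.zeros(d)

        vs = {"orth": v_orth}
        gs = {"orth": g_orth}

        if self.pam_present:
            gx, gy = c["allo_center"]
            wA = c["allo_width"]
            dpx, dpy = px - gx, py - gy
            Gp = math.exp(-(dpx * dpx + dpy * dpy) / (2.0 * wA * wA))
            v_allo = -c["allo_depth"] * Gp
            g_allo = np.zeros(d)
            g_allo[2] = c["allo_depth"] * Gp * dpx / (wA * wA)
            g_allo[3] = c["allo_depth"] * Gp * dpy / (wA * wA)
            Lp = c["pam_wall_radius"]
            rp2 = px * px + py * py
            kp = c["pam_wall_strength"] / Lp**8
            v_allo += kp * rp2**4
            g_allo[2] += kp * 8.0 * rp2**3 * px
            g_allo[3] += kp * 8.0 * rp2**3 * py
            vs["allo"] = v_allo
            gs["allo"] = g_allo

            if c["c1"] > 0:
                wo = c["occupancy_coupling_width"]
                Wocc = math.exp(-(dpx * dpx + dpy * dpy) / (2.0 * wo * wo))
                sc, wc = c["sb_minima"][0], c["sb_widths"][0]
                Gc = math.exp(-((s - sc) ** 2) / (2.0 * wc * wc))
                v_sb -= c["c1"] * Wocc * Gc
                dvds += c["c1"] * Wocc * Gc * (s - sc) / (wc * wc)
                g_sb[2] = c["c1"] * Wocc * Gc * dpx / (wo * wo)
                g_sb[3] = c["c1"] * Wocc * Gc * dpy / (wo * wo)

        g_sb[si] = dvds
        vs["sb"] = v_sb
        gs["sb"] = g_sb
        return vs, gs

    def energy(self, x: np.ndarray) -> float:
        vs, _ = self.energy_and_gradient_terms(x)
        return float(sum(vs.values()))

    def gradient(self, x: np.ndarray) -> np.ndarray:
        _, gs = self.energy_and_gradient_terms(x)
        return sum(gs.values())

    @property
    def domain_bounds(self) -> tuple[tuple[float, float], ...]:
        c = self.config
        La, Lp = c["agonist_wall_radius"], c["pam_wall_radius"]
        lo, hi = c["sb_domain"]
        a = ((-1.3 * La, 1.3 * La),) * 2
        if self.pam_present:
            return a + ((-1.3 * Lp, 1.3 * Lp),) * 2 + ((lo, hi),)
        return a + ((lo, hi),)

    @property
    def start(self) -> np.ndarray:
        """Deterministic initial coordinates: agonist bound, PAM unbound,
        salt bridge intermediate."""
        c = self.config
        x = [c["orth_center"][0], c["orth_center"][1]]
        if self.pam_present:
            x += [-2.0, 0.0]
        x += [c["sb_minima"][1]]
        return np.array(x, dtype=float)

    # -- analysis helpers ----------------------------------------------
    def occupancy(self, pam_coords: np.ndarray) -> np.ndarray:
        """Hard site-membership indicator (1 inside ``site_radius`` of the
        allosteric well center)."""
        c = self.config
        center = np.asarray(c["allo_center"])
        d = np.linalg.norm(np.atleast_2d(pam_coords) - center, axis=1)
        return (d <= c["site_radius"]).astype(int)

    # -- serialization --------------------------------------------------
    def to_config(self) -> dict:
        out = {}
        for k, v in self.config.items():
            if isinstance(v, tuple):
                v = list(v)
            if k == "secondary_wells":
                v = [{**sw, "center": list(sw["center"])} for sw in v]
            out[k] = v
        return out

    @classmethod
    def from_config(cls, config: dict) -> "AllostericToySystem":
        return cls(config=dict(config))


def make_allosteric_toy(config: dict | None = None, **overrides) -> AllostericToySystem:
    """Build an :class:`AllostericToySystem` from defaults plus overrides.

    ``config`` (a mapping, e.g. loaded from YAML) is applied first, keyword
    overrides second.  Raises on ill-ordered salt-bridge minima or
    non-positive well depths.
    """
    cfg = dict(config) if config else {}
    cfg.update(overrides)
    return AllostericToySystem(config=cfg)


# ---------------------------------------------------------------------------
# exact Boltzmann oracles
# ---------------------------------------------------------------------------

def exact_pmf(potential: ToyPotential, cv_edges, temperature: float = 1.0,
              subdivisions: int = 200) -> PMF:
    """Exact PMF of a 1D or 2D potential by direct Boltzmann quadrature.

    Each bin is subdivided into ``subdivisions`` midpoints per dimension; the
    density exp(−βV) is integrated by the midpoint rule and converted to a
    min-shifted free energy −k_B T ln p(A) (probability density per bin, so
    unequal bin widths are handled).  The grid must lie inside the potential's
    domain bounds.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    beta = 1.0 / temperature
    if isinstance(cv_edges, np.ndarray) or (
            len(cv_edges) and np.isscalar(cv_edges[0])):
        edges = (np.asarray(cv_edges, dtype=float),)
    else:
        edges = tuple(np.asarray(e, dtype=float) for e in cv_edges)
    if len(edges) != potential.dimensionality:
        raise ValueError("edge arrays must match the potential dimensionality")
    for e, (lo, hi) in zip(edges, potential.domain_bounds):
        if e[0] < lo - 1e-12 or e[-1] > hi + 1e-12:
            raise ValueError("cv grid extends outside the potential domain")

    def fine_points(e):
        pts = []
        for i in range(len(e) - 1):
            sub = np.linspace(e[i], e[i + 1], subdivisions, endpoint=False)
            sub = sub + (e[i + 1] - e[i]) / (2 * subdivisions)
            pts.append(sub)
        return np.concatenate(pts)

    if len(edges) == 1:
        xs = fine_points(edges[0])
        v = np.array([potential.energy(np.array([x])) for x in xs])
        w = np.exp(-beta * (v - v.min()))
        nb = len(edges[0]) - 1
        mass = w.reshape(nb, subdivisions).sum(axis=1)
        mass = mass / mass.sum()
        widths = np.diff(edges[0])
        shape = (nb,)
    else:
        xs = fine_points(edges[0])
        ys = fine_points(edges[1])
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        v = np.array([[potential.energy(np.array([x, y])) for y in ys] for x in xs])
        w = np.exp(-beta * (v - v.min()))
        nb1, nb2 = len(edges[0]) - 1, len(edges[1]) - 1
        mass = w.reshape(nb1, subdivisions, nb2, subdivisions).sum(axis=(1, 3))
        mass = mass / mass.sum()
        widths = np.outer(np.diff(edges[0]), np.diff(edges[1]))
        shape = (nb1, nb2)

    density = mass / widths
    with np.errstate(divide="ignore"):
        f = -temperature * np.log(density)
    f = f - np.nanmin(f[np.isfinite(f)])
    return PMF(
        dimensionality=len(edges),
        bin_edges=edges,
        free_energy=f,
        reweighted_probability=mass,
        biased_probability=mass,
        temperature=temperature,
        label=f"exact:{potential.label}",
    )


# -- oracles over the allosteric toy ---------------------------------------

def _agonist_grid(system: AllostericToySystem, n: int = 161):
    L = 1.25 * system.config["agonist_wall_radius"]
    g = np.linspace(-L, L, n)
    return np.meshgrid(g, g, indexing="ij")


def _pam_grid(system: AllostericToySystem, n: int = 161):
    L = 1.25 * system.config["pam_wall_radius"]
    g = np.linspace(-L, L, n)
    return np.meshgrid(g, g, indexing="ij")


def boltzmann_marginal_s(system: AllostericToySystem, s_grid: np.ndarray,
                         pam_fixed=None, n_quad: int = 121) -> np.ndarray:
    """Exact marginal Boltzmann density of the salt-bridge coordinate.

    Integrates the full Boltzmann weight over the agonist plane (and the PAM
    plane unless ``pam_fixed`` pins the PAM).  Returns a density normalized
    over ``s_grid`` by the trapezoid rule.
    """
    beta = 1.0 / system.temperature
    s_grid = np.asarray(s_grid, dtype=float)
    AX, AY = _agonist_grid(system, n_quad)
    if system.pam_present and pam_fixed is None:
        PX, PY = _pam_grid(system, n_quad)
        w_allo = np.exp(-beta * system._allo_energy(PX, PY))
    out = np.empty_like(s_grid)
    for i, s in enumerate(s_grid):
        za = np.exp(-beta * system._orth_energy(AX, AY, s)).sum()
        if not system.pam_present:
            zb = np.exp(-beta * system._sb_base_energy(s))
        elif pam_fixed is not None:
            px, py = pam_fixed
            zb = np.exp(-beta * system._sb_energy(s, px, py))
        else:
            # the c1 coupling links s and the PAM plane; integrate jointly
            zb = (w_allo * np.exp(-beta * system._sb_energy(s, PX, PY))).sum()
        out[i] = za * zb
    norm = np.trapezoid(out, s_grid)
    return out / norm


def boltzmann_mean_s(system: AllostericToySystem, pam_fixed=None,
                     n_s: int = 361, n_quad: int = 121) -> float:
    """Boltzmann-mean of the salt-bridge coordinate by quadrature."""
    lo, hi = system.config["sb_domain"]
    s = np.linspace(lo, hi, n_s)
    p = boltzmann_marginal_s(system, s, pam_fixed=pam_fixed, n_quad=n_quad)
    return float(np.trapezoid(s * p, s))


def boltzmann_agonist_stats(system: AllostericToySystem, s_fixed: float,
                            n_quad: int = 241):
    """Mean and covariance of the agonist position at fixed salt-bridge
    coordinate, by 2D quadrature of the Boltzmann weight."""
    beta = 1.0 / system.temperature
    AX, AY = _agonist_grid(system, n_quad)
    w = np.exp(-beta * system._orth_energy(AX, AY, s_fixed))
    w = w / w.sum()
    mx = (w * AX).sum()
    my = (w * AY).sum()
    cxx = (w * (AX - mx) ** 2).sum()
    cyy = (w * (AY - my) ** 2).sum()
    cxy = (w * (AX - mx) * (AY - my)).sum()
    return np.array([mx, my]), np.array([[cxx, cxy], [cxy, cyy]])


def boltzmann_joint_s_displacement(system: AllostericToySystem,
                                   s_edges: np.ndarray, r_edges: np.ndarray,
                                   n_quad: int = 201, n_s_sub: int = 8) -> PMF:
    """Exact joint PMF over (salt-bridge s, agonist displacement |a − c_orth|)
    for a PAM-free system, by quadrature over the agonist plane.
    """
    if system.pam_present:
        raise ValueError("joint oracle is defined for the PAM-free system")
    beta = 1.0 / system.temperature
    s_edges = np.asarray(s_edges, dtype=float)
    r_edges = np.asarray(r_edges, dtype=float)
    AX, AY = _agonist_grid(system, n_quad)
    cx, cy = system.config["orth_center"]
    R = np.sqrt((AX - cx) ** 2 + (AY - cy) ** 2).ravel()
    r_idx = np.digitize(R, r_edges) - 1
    nb_r = len(r_edges) - 1
    in_r = (r_idx >= 0) & (r_idx < nb_r)
    nb_s = len(s_edges) - 1
    mass = np.zeros((nb_s, nb_r))
    for i in range(nb_s):
        subs = np.linspace(s_edges[i], s_edges[i + 1], n_s_sub, endpoint=False)
        subs = subs + (s_edges[i + 1] - s_edges[i]) / (2 * n_s_sub)
        for s in subs:
            w = np.exp(-beta * (system._orth_energy(AX, AY, s)
                                + system._sb_base_energy(s))).ravel()
            mass[i] += np.bincount(r_idx[in_r], weights=w[in_r], minlength=nb_r)
    mass = mass / mass.sum()
    with np.errstate(divide="ignore"):
        f = -system.temperature * np.log(mass)
    f = f - f[np.isfinite(f)].min()
    f[~np.isfinite(f)] = np.nan
    return PMF(
        dimensionality=2,
        bin_edges=(s_edges, r_edges),
        free_energy=f,
        reweighted_probability=mass,
        biased_probability=mass,
        mask=np.isfinite(f),
        temperature=system.temperature,
        label="exact:(s, agonist displacement)",
    )
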