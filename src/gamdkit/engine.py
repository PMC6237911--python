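"""Langevin dynamics with the Gaussian-accelerated-MD harmonic boost.

The boost potential adds ΔV(r) = ½ k (E − V(r))² whenever the potential V
falls below a threshold E, flattening the landscape while keeping ΔV
near-Gaussian so the canonical ensemble can be recovered by cumulant
reweighting.  The threshold and effective force constant are chosen
adaptively from running potential statistics:

* E must satisfy  V_max ≤ E ≤ V_min + 1/k,
* k = k0 / (V_max − V_min) with 0 < k0 ≤ 1,
* lower bound  (E = V_max):  k0 = min(1, (σ0/σ_V)·(V_max−V_min)/(V_max−V_avg)),
* upper bound  (E = V_min + 1/k):  k0'' = (1 − σ0/σ_V)·(V_max−V_min)/(V_max−V_avg),
  accepted only if 0 < k0'' ≤ 1, otherwise the lower-bound formula is used.

σ0 is the user ceiling on the boost-potential standard deviation
(default 6 k_B T here; typical practice quotes ~10 k_B T for all-atom runs).

A run proceeds in three phases mirroring standard practice: a conventional-MD
phase that only collects potential statistics, an equilibration phase with
the boost applied and E/k0 periodically refreshed, and production with frozen
boost parameters and per-frame ΔV bookkeeping for reweighting.

Boost modes: ``none`` (plain Langevin), ``total`` (boost on the total
potential), ``component`` (boost on a named subset of energy terms — the
"dihedral-analog"), and ``dual`` (independent boosts on the component and the
total potential, the per-frame ΔV being their sum).

Integrator: BAOAB-split Langevin with unit masses, fixed timestep and an
explicit seed; one gradient evaluation and one Gaussian vector per step, so
runs are bitwise reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PotentialStats",
    "BoostParams",
    "SimulationConfig",
    "Trajectory",
    "EngineState",
    "update_stats",
    "compute_k0",
    "compute_boost",
    "boosted_force",
    "run_phase",
    "run_gamd",
]

PHASES = ("cmd", "equilibration", "production")


# ---------------------------------------------------------------------------
# potential statistics (single-pass min/max/mean/variance)
# ---------------------------------------------------------------------------

@dataclass
class PotentialStats:
    """Running min/max/mean/std of a potential energy (Welford update)."""

    v_min: float = math.inf
    v_max: float = -math.inf
    v_avg: float = 0.0
    _m2: float = 0.0
    n_samples: int = 0

    @property
    def sigma_v(self) -> float:
        """Population standard deviation of the observed energies."""
        if self.n_samples < 1:
            return 0.0
        return math.sqrt(self._m2 / self.n_samples)

    def update(self, v: float) -> "PotentialStats":
        if not math.isfinite(v):
            raise ValueError(f"non-finite potential energy: {v}")
        self.n_samples += 1
        if v < self.v_min:
            self.v_min = v
        if v > self.v_max:
            self.v_max = v
        delta = v - self.v_avg
        self.v_avg += delta / self.n_samples
        self._m2 += delta * (v - self.v_avg)
        return self

    def as_dict(self) -> dict:
        return {
            "v_min": self.v_min,
            "v_max": self.v_max,
            "v_avg": self.v_avg,
            "sigma_v": self.sigma_v,
            "n_samples": self.n_samples,
        }


def update_stats(stats: PotentialStats, v: float) -> PotentialStats:
    """Update running potential statistics with one energy value (in place)."""
    return stats.update(v)


# ---------------------------------------------------------------------------
# boost parameters
# ---------------------------------------------------------------------------

@dataclass
class BoostParams:
    """Threshold E and force constant for one boosted energy component.

    ``k0`` is the dimensionless effective force constant in (0, 1];
    ``k = k0 / (V_max − V_min)`` has units of 1/energy.  ``bound_mode``
    records the requested threshold placement; ``effective_bound`` what was
    actually used (the upper-bound formula falls back to the lower bound when
    its k0'' leaves (0, 1]).
    """

    E: float
    k0: float
    k: float
    sigma0: float
    bound_mode: str = "lower"
    effective_bound: str = "lower"

    def as_dict(self) -> dict:
        return asdict(self)


def compute_k0(stats: PotentialStats, sigma0: float,
               bound_mode: str = "lower") -> BoostParams:
    """Choose the boost threshold and force constant from potential statistics.

    Implements the lower-bound rule (E = V_max, k0 clamped to 1) and the
    upper-bound rule (E = V_min + 1/k) with automatic fallback to the lower
    bound when the upper-bound k0'' is outside (0, 1].
    """
    if bound_mode not in ("lower", "upper"):
        raise ValueError(f"unknown bound_mode: {bound_mode!r}")
    if sigma0 <= 0:
        raise ValueError("sigma0 must be positive")
    if stats.n_samples < 2:
        raise ValueError("need at least two potential samples")
    vmax, vmin, vavg, sv = stats.v_max, stats.v_min, stats.v_avg, stats.sigma_v
    if vmax <= vmin:
        raise ValueError("degenerate statistics: V_max equals V_min")
    if vmax <= vavg:
        raise ValueError("degenerate statistics: V_max equals V_avg")
    if sv <= 0:
        raise ValueError("degenerate statistics: sigma_V is zero")

    spread = (vmax - vmin) / (vmax - vavg)
    k0_lower = min(1.0, (sigma0 / sv) * spread)

    if bound_mode == "upper":
        k0pp = (1.0 - sigma0 / sv) * spread
        if 0.0 < k0pp <= 1.0:
            k = k0pp / (vmax - vmin)
            return BoostParams(E=vmin + 1.0 / k, k0=k0pp, k=k,
                               sigma0=sigma0, bound_mode="upper",
                               effective_bound="upper")
    k = k0_lower / (vmax - vmin)
    return BoostParams(E=vmax, k0=k0_lower, k=k, sigma0=sigma0,
                       bound_mode=bound_mode, effective_bound="lower")


def compute_boost(v: float, params: BoostParams) -> float:
    """Harmonic boost energy ΔV = ½ k (E − v)² for v < E, else 0."""
    if v >= params.E:
        return 0.0
    d = params.E - v
    return 0.5 * params.k * d * d


def boosted_force(grad_v: np.ndarray, v: float, params: BoostParams) -> np.ndarray:
    """Force on the boosted surface V* = V + ΔV.

    For v < E the unbiased force −∇V is scaled by (1 − k(E − v)); the scale
    lies in [0, 1] whenever E is inside its admissible range, reaching 0 in
    the fully flattened limit k(E − v) = 1.
    """
    grad_v = np.asarray(grad_v, dtype=float)
    if v >= params.E:
        return -grad_v
    return -grad_v * (1.0 - params.k * (params.E - v))


# ---------------------------------------------------------------------------
# configuration / trajectory containers
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Langevin/GaMD run settings (reduced units)."""

    timestep: float = 0.01
    friction: float = 1.0
    temperature: float = 1.0
    n_steps_cmd: int = 2000
    n_steps_equil: int = 20000
    n_steps_production: int = 100000
    save_stride: int = 10
    seed: int = 0
    boost_mode: str = "total"            # none | total | component | dual
    component_terms: tuple[str, ...] | None = None   # "dihedral-analog" term names
    sigma0: float = 6.0
    bound_mode: str = "lower"
    refresh_stride: int = 1000           # E/k0 refresh cadence in equilibration
    k0_override: float | None = None     # force k0 (testing; 0 disables the boost)
    x0: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.boost_mode not in ("none", "total", "component", "dual"):
            raise ValueError(f"unknown boost_mode: {self.boost_mode!r}")
        if self.boost_mode in ("component", "dual") and not self.component_terms:
            raise ValueError("component/dual boost requires component_terms")
        for name in ("n_steps_cmd", "n_steps_equil", "n_steps_production"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.save_stride < 1:
            raise ValueError("save_stride must be >= 1")
        if self.timestep <= 0 or self.friction < 0 or self.temperature <= 0:
            raise ValueError("timestep/temperature must be positive, friction >= 0")

    def boosted_keys(self) -> tuple[str, ...]:
        if self.boost_mode == "none":
            return ()
        if self.boost_mode == "total":
            return ("total",)
        if self.boost_mode == "component":
            return ("component",)
        return ("component", "total")

    def as_dict(self) -> dict:
        d = asdict(self)
        if d["component_terms"] is not None:
            d["component_terms"] = list(d["component_terms"])
        return d


@dataclass
class Trajectory:
    """Saved frames of one phase plus the boost bookkeeping for reweighting."""

    phase: str
    step: np.ndarray                 # global step index of each saved frame
    coords: np.ndarray               # (n_frames, dim)
    v_total: np.ndarray
    v_terms: dict[str, np.ndarray]
    dv_total: np.ndarray
    dv_parts: dict[str, np.ndarray]  # per boosted key ("total"/"component")
    config: SimulationConfig | None = None
    final_params: dict[str, BoostParams] = field(default_factory=dict)
    final_stats: dict[str, dict] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.step)

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        data = {"step": self.step}
        for d in range(self.dim):
            data[f"x{d}"] = self.coords[:, d]
        data["v_total"] = self.v_total
        for name, v in self.v_terms.items():
            data[f"v_{name}"] = v
        data["dv_total"] = self.dv_total
        for name, v in self.dv_parts.items():
            data[f"dv_part_{name}"] = v
        return pd.DataFrame(data)

    def save(self, prefix) -> None:
        """Write a columnar CSV of frames plus a JSON sidecar with config,
        final boost parameters and statistics."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(prefix.with_suffix(".csv"), index=False)
        side = {
            "phase": self.phase,
            "config": self.config.as_dict() if self.config else None,
            "final_params": {k: p.as_dict() for k, p in self.final_params.items()},
            "final_stats": self.final_stats,
        }
        prefix.with_suffix(".json").write_text(json.dumps(side, indent=2))

    @classmethod
    def load(cls, prefix) -> "Trajectory":
        prefix = Path(prefix)
        df = pd.read_csv(prefix.with_suffix(".csv"))
        side = json.loads(prefix.with_suffix(".json").read_text())
        xcols = sorted((c for c in df.columns if c.startswith("x")
                        and c[1:].isdigit()), key=lambda c: int(c[1:]))
        v_terms = {c[2:]: df[c].to_numpy() for c in df.columns
                   if c.startswith("v_") and c != "v_total"}
        dv_parts = {c[len("dv_part_"):]: df[c].to_numpy() for c in df.columns
                    if c.startswith("dv_part_")}
        cfg = None
        if side.get("config"):
            c = dict(side["config"])
            if c.get("component_terms") is not None:
                c["component_terms"] = tuple(c["component_terms"])
            if c.get("x0") is not None:
                c["x0"] = tuple(c["x0"])
            cfg = SimulationConfig(**c)
        params = {k: BoostParams(**p) for k, p in side.get("final_params", {}).items()}
        return cls(
            phase=side.get("phase", "production"),
            step=df["step"].to_numpy(),
            coords=df[xcols].to_numpy(),
            v_total=df["v_total"].to_numpy(),
            v_terms=v_terms,
            dv_total=df["dv_total"].to_numpy(),
            dv_parts=dv_parts,
            config=cfg,
            final_params=params,
            final_stats=side.get("final_stats", {}),
        )


@dataclass
class EngineState:
    """Mutable state threaded through the cmd → equilibration → production phases."""

    x: np.ndarray
    v: np.ndarray
    rng: np.random.Generator
    stats: dict[str, PotentialStats]
    params: dict[str, BoostParams] = field(default_factory=dict)
    step: int = 0
    phases_done: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# phase runner
# ---------------------------------------------------------------------------

def _component_value(v_terms: dict, g_terms: dict, names) -> tuple[float, np.ndarray]:
    v = 0.0
    g = None
    for n in names:
        v += v_terms[n]
        g = g_terms[n] if g is None else g + g_terms[n]
    return v, g


def _refresh_params(state: EngineState, config: SimulationConfig) -> None:
    for key in config.boosted_keys():
        if config.k0_override is not None:
            st = state.stats[key]
            vmax, vmin = st.v_max, st.v_min
            k0 = float(config.k0_override)
            k = k0 / (vmax - vmin) if vmax > vmin else 0.0
            state.params[key] = BoostParams(E=vmax, k0=k0, k=k,
                                            sigma0=config.sigma0,
                                            bound_mode=config.bound_mode,
                                            effective_bound="lower")
        else:
            state.params[key] = compute_k0(state.stats[key], config.sigma0,
                                           config.bound_mode)


def run_phase(system, config: SimulationConfig, phase: str,
              state: EngineState | None = None) -> tuple[Trajectory, EngineState]:
    """Run one simulation phase and return its saved frames plus the state.

    ``system`` is any object exposing ``dimensionality``,
    ``energy_and_gradient_terms(x)`` (and optionally ``start``): toy
    potentials and the allosteric toy system both qualify.  Phases must be
    started in the order cmd → equilibration → production; production without
    prior statistics collection raises.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase: {phase!r}")
    boosted = config.boosted_keys()
    comp_names = config.component_terms or ()
    if comp_names:
        missing = set(comp_names) - set(system.term_names)
        if missing:
            raise ValueError(f"unknown component term(s): {sorted(missing)}")

    if state is None:
        if phase != "cmd":
            raise ValueError("a fresh run must start with the cmd phase")
        x0 = np.asarray(config.x0, dtype=float) if config.x0 is not None \
            else np.array(getattr(system, "start", np.zeros(system.dimensionality)),
                          dtype=float)
        state = EngineState(
            x=x0.copy(),
            v=np.zeros(system.dimensionality),
            rng=np.random.default_rng(config.seed),
            stats={k: PotentialStats() for k in ("total", "component")},
        )
    if phase == "production" and boosted:
        if any(state.stats[k].n_samples < 2 for k in boosted):
            raise ValueError("production requires potential statistics "
                             "(run cmd/equilibration first)")

    apply_boost = phase in ("equilibration", "production") and bool(boosted)
    collect_stats = phase in ("cmd", "equilibration")
    if apply_boost and (phase == "production") and not all(
            k in state.params for k in boosted):
        _refresh_params(state, config)
    if apply_boost and phase == "equilibration":
        _refresh_params(state, config)

    n_steps = {"cmd": config.n_steps_cmd,
               "equilibration": config.n_steps_equil,
               "production": config.n_steps_production}[phase]
    dt = config.timestep
    a = math.exp(-config.friction * dt)
    b = math.sqrt(config.temperature * (1.0 - a * a))
    dim = system.dimensionality
    half_dt = 0.5 * dt

    x = state.x
    v = state.v
    rng = state.rng
    stats = state.stats

    track_comp = bool(comp_names)

    def eval_force(xv):
        """Return (v_tot, v_comp, f, dv_parts_dict)."""
        v_terms, g_terms = system.energy_and_gradient_terms(xv)
        v_tot = 0.0
        g_tot = None
        for val in v_terms.values():
            v_tot += val
        for g in g_terms.values():
            g_tot = g.copy() if g_tot is None else g_tot + g
        v_comp = 0.0
        g_comp = None
        if track_comp:
            v_comp, g_comp = _component_value(v_terms, g_terms, comp_names)
        f = -g_tot
        dv = {}
        if apply_boost:
            for key in boosted:
                p = state.params[key]
                vk = v_tot if key == "total" else v_comp
                gk = g_tot if key == "total" else g_comp
                if vk < p.E:
                    f = f + p.k * (p.E - vk) * gk
                    d = p.E - vk
                    dv[key] = 0.5 * p.k * d * d
                else:
                    dv[key] = 0.0
        return v_tot, v_comp, f, dv, v_terms

    # storage
    rec_step, rec_x, rec_vt, rec_dvt = [], [], [], []
    rec_vterms: dict[str, list] = {n: [] for n in system.term_names}
    rec_dvparts: dict[str, list] = {k: [] for k in boosted}

    v_tot, v_comp, f, dv, v_terms = eval_force(x)

    def record(step_idx):
        rec_step.append(step_idx)
        rec_x.append(x.copy())
        rec_vt.append(v_tot)
        for n in rec_vterms:
            rec_vterms[n].append(v_terms[n])
        tot = 0.0
        for k in boosted:
            val = dv.get(k, 0.0)
            rec_dvparts[k].append(val)
            tot += val
        rec_dvt.append(tot)

    for i in range(n_steps):
        # BAOAB: B(half) A(half) O A(half) B(half); one force/noise per step
        v += half_dt * f
        x += half_dt * v
        v *= a
        v += b * rng.standard_normal(dim)
        x += half_dt * v
        v_tot, v_comp, f, dv, v_terms = eval_force(x)
        v += half_dt * f

        state.step += 1
        if collect_stats:
            stats["total"].update(v_tot)
            if track_comp:
                stats["component"].update(v_comp)
            if phase == "equilibration" and apply_boost and \
                    (i + 1) % config.refresh_stride == 0:
                _refresh_params(state, config)
                # ΔV bookkeeping reflects the refreshed parameters
                v_tot, v_comp, f, dv, v_terms = eval_force(x)
        if (i + 1) % config.save_stride == 0:
            record(state.step)

    if phase == "equilibration" and boosted:
        _refresh_params(state, config)   # frozen for production

    state.phases_done = state.phases_done + (phase,)
    traj = Trajectory(
        phase=phase,
        step=np.asarray(rec_step, dtype=int),
        coords=np.asarray(rec_x) if rec_x else np.empty((0, dim)),
        v_total=np.asarray(rec_vt),
        v_terms={n: np.asarray(v) for n, v in rec_vterms.items()},
        dv_total=np.asarray(rec_dvt),
        dv_parts={k: np.asarray(v) for k, v in rec_dvparts.items()},
        config=config,
        final_params={k: state.params[k] for k in boosted if k in state.params},
        final_stats={k: stats[k].as_dict() for k in
                     (("total", "component") if track_comp else ("total",))},
    )
    return traj, state


def run_gamd(system, config: SimulationConfig) -> dict:
    """Convenience driver: cmd → equilibration → production.

    Returns a dict with the three phase trajectories and the final state;
    ``result["production"]`` carries the frozen boost parameters used for
    reweighting.
    """
    traj_cmd, state = run_phase(system, config, "cmd")
    traj_eq, state = run_phase(system, config, "equilibration", state)
    traj_prod, state = run_phase(system, config, "production", state)
    return {"cmd": traj_cmd, "equilibration": traj_eq,
            "production": traj_prod, "state": state}
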