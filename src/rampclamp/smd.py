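"""Coarse-grained steered Langevin engine with the ramp→clamp protocol.

The molecular system is an elastic-network model (ENM): Cα beads joined
by harmonic springs at their native separations.  A virtual spring
(stiffness 34.74 pN/nm by default) tethers the steered bead to a dummy
point pulled at constant velocity (5 Å/ns default) along a direction set
by the loading mode at t = 0:

* mode 1 — one fixed bead; pulling direction runs from the fixed bead to
  the steered bead;
* mode 2 — two fixed beads; pulling direction runs from the midpoint of
  the fixed pair to the steered bead.

When the spring tension first reaches the clamp setpoint (25 pN default)
the protocol switches to force clamp: the same constant force is applied
to the steered bead for the remaining duration.  Free beads follow
overdamped (Brownian) Langevin dynamics; inter-chain "interface" springs
may be declared breakable and are removed once stretched past a breakage
factor (engine-specific rupture rule, 2× rest length by default).

Internally forces are kcal/mol/Å; the trace reports pN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.spatial import cKDTree

from .errors import ConfigurationError, DegenerateGeometryError, StabilityError
from .structures import ForceTrace, Structure, Trajectory
from .units import KB, KCAL_PER_MOL_PER_A_TO_PN, spring_pn_per_nm_to_kcal


@dataclass
class ENMModel:
    """Elastic-network model over Cα beads."""

    coords: np.ndarray            # (N, 3) Å, native geometry
    masses: np.ndarray            # (N,) amu (bookkeeping only; overdamped)
    springs: np.ndarray           # (M, 2) bead index pairs, i < j
    rest_lengths: np.ndarray      # (M,) Å
    stiffness: np.ndarray         # (M,) kcal/mol/Å²
    breakable: np.ndarray         # (M,) bool — interface springs
    atoms: Optional[Structure] = None

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]


@dataclass
class LoadingProtocol:
    """Pulling-protocol parameters (study-standard defaults)."""

    mode: int = 2
    k_spring_pn_nm: float = 34.74
    v_pull_a_ns: float = 5.0
    clamp_force_pn: float = 25.0
    temperature_k: float = 300.0
    friction: float = 0.005       # kcal·ns/(mol·Å²)
    dt_ns: float = 1.0e-5
    ramp_duration_ns: float = 1.0
    clamp_duration_ns: float = 1.0
    seed: int = 0
    sample_stride: int = 100
    break_factor: float = 2.0     # breakable springs snap at this × rest length
    recompute_direction: bool = False

    def __post_init__(self):
        if self.k_spring_pn_nm <= 0 or self.v_pull_a_ns <= 0 \
                or self.clamp_force_pn <= 0:
            raise ConfigurationError("spring, velocity and clamp force must be > 0")
        if self.mode not in (1, 2):
            raise ConfigurationError("loading mode must be 1 or 2")


@dataclass
class ConfiguredSystem:
    """An ENM plus anchors, steered bead and pulling direction."""

    model: ENMModel
    protocol: LoadingProtocol
    fixed: np.ndarray             # bead indices
    steered: int
    direction: np.ndarray         # unit vector, set from t = 0 geometry


@dataclass
class RuptureResult:
    rupture_force: float          # pN
    rupture_time: float           # ns
    smoothed: np.ndarray


@dataclass
class SMDResult:
    trajectory: Trajectory
    trace: ForceTrace
    completed: bool               # clamp trigger reached (ramp runs)
    switch_time_ns: Optional[float] = None
    work_spring_kcal: float = 0.0
    dissipation_kcal: float = 0.0
    broken_springs: int = 0


def build_enm(structure: Structure, ca_only: bool = True, cutoff: float = 10.0,
              k_enm: float = 1.0, k_interface: Optional[float] = None,
              interface_breakable: bool = True) -> ENMModel:
    """Build an elastic network from a structure.

    Springs connect every bead pair within ``cutoff`` Å at their native
    distance.  Pairs spanning two chains get stiffness ``k_interface``
    (default ``k_enm / 10``) and are breakable when
    ``interface_breakable`` is set, so that pulling can rupture the
    complex.
    """
    if ca_only:
        idx = [i for i, a in enumerate(structure.atoms) if a.name == "CA"]
        if not idx:
            idx = list(range(structure.n_atoms))
    else:
        idx = list(range(structure.n_atoms))
    sub = structure.subset(idx)
    X = sub.coords
    n = X.shape[0]
    if n < 2:
        raise DegenerateGeometryError("an ENM needs at least 2 beads")
    if k_interface is None:
        k_interface = k_enm / 10.0
    chains = np.array([a.chain_id for a in sub.atoms])
    tree = cKDTree(X)
    pairs = sorted(tree.query_pairs(cutoff))
    springs, rests, ks, brk = [], [], [], []
    for i, j in pairs:
        springs.append((i, j))
        rests.append(float(np.linalg.norm(X[i] - X[j])))
        inter = chains[i] != chains[j]
        ks.append(k_interface if inter else k_enm)
        brk.append(bool(inter and interface_breakable))
    springs = np.array(springs, dtype=int).reshape(-1, 2)
    degree = np.zeros(n, dtype=int)
    for i, j in springs:
        degree[i] += 1
        degree[j] += 1
    if np.any(degree == 0):
        warnings.warn(
            f"{int(np.sum(degree == 0))} bead(s) have no springs "
            f"(cutoff {cutoff} Å too small?)", stacklevel=2)
    return ENMModel(coords=X.copy(), masses=sub.masses,
                    springs=springs, rest_lengths=np.array(rests),
                    stiffness=np.array(ks), breakable=np.array(brk, dtype=bool),
                    atoms=sub)


def set_loading(model: ENMModel, protocol: LoadingProtocol,
                fixed: Sequence[int], steered: int) -> ConfiguredSystem:
    """Configure anchors and the pulling direction from the t=0 geometry.

    Mode 1 requires one fixed bead (direction fixed→steered); mode 2
    requires two (direction from the midpoint of the fixed pair to the
    steered bead).  The direction is held constant for the whole run
    unless ``protocol.recompute_direction`` is set.
    """
    fixed = np.asarray(list(fixed), dtype=int)
    if steered in set(fixed.tolist()):
        raise ConfigurationError("steered bead cannot be in the fixed set")
    need = 1 if protocol.mode == 1 else 2
    if len(fixed) != need:
        raise ConfigurationError(
            f"loading mode {protocol.mode} needs exactly {need} fixed bead(s)")
    if np.any(fixed >= model.n_beads) or steered >= model.n_beads:
        raise ConfigurationError("anchor index out of range")
    anchor = model.coords[fixed].mean(axis=0)
    d = model.coords[steered] - anchor
    norm = np.linalg.norm(d)
    if norm < 1e-9:
        raise DegenerateGeometryError("steered bead coincides with the anchor point")
    return ConfiguredSystem(model=model, protocol=protocol, fixed=fixed,
                            steered=int(steered), direction=d / norm)


# ------------------------------------------------------------ integrator

def enm_forces(X: np.ndarray, springs: np.ndarray, rests: np.ndarray,
               ks: np.ndarray, alive: np.ndarray) -> np.ndarray:
    """Harmonic network forces (kcal/mol/Å)."""
    F = np.zeros_like(X)
    if springs.shape[0] == 0:
        return F
    i, j = springs[:, 0], springs[:, 1]
    dv = X[j] - X[i]
    L = np.linalg.norm(dv, axis=1)
    L = np.where(L < 1e-12, 1e-12, L)
    mag = ks * (L - rests) * alive  # pull back toward rest length
    f = (mag / L)[:, None] * dv
    np.add.at(F, i, f)
    np.add.at(F, j, -f)
    return F


def enm_potential(X: np.ndarray, springs: np.ndarray, rests: np.ndarray,
                  ks: np.ndarray, alive: np.ndarray) -> float:
    if springs.shape[0] == 0:
        return 0.0
    L = np.linalg.norm(X[springs[:, 1]] - X[springs[:, 0]], axis=1)
    return float(np.sum(0.5 * ks * (L - rests) ** 2 * alive))


def _check_stability(protocol: LoadingProtocol, k_max_kcal: float) -> None:
    # explicit overdamped Euler is stable for dt < 2 γ / k; keep a margin
    limit = 0.5 * protocol.friction / max(k_max_kcal, 1e-12)
    if protocol.dt_ns > limit:
        raise StabilityError(
            f"dt {protocol.dt_ns:g} ns too large for stiffness "
            f"{k_max_kcal:g} kcal/mol/Å²; use dt ≤ {limit:g} ns"
        )


class _Engine:
    """Shared integration state for ramp and clamp phases."""

    def __init__(self, system: ConfiguredSystem, x0: Optional[np.ndarray] = None,
                 rigid_steered: bool = False):
        self.sys = system
        p = system.protocol
        m = system.model
        k_spring_kcal = spring_pn_per_nm_to_kcal(p.k_spring_pn_nm)
        k_max = max(float(m.stiffness.max(initial=0.0)) * 2.0, k_spring_kcal)
        _check_stability(p, k_max)
        self.k_spring_kcal = k_spring_kcal
        self.X = (m.coords if x0 is None else x0).astype(float).copy()
        self.alive = np.ones(m.springs.shape[0])
        self.mobile = np.ones(m.n_beads, dtype=bool)
        self.mobile[system.fixed] = False
        if rigid_steered:
            self.mobile[system.steered] = False
        self.rng = np.random.default_rng(p.seed)
        self.noise_sigma = np.sqrt(2.0 * KB * p.temperature_k * p.dt_ns
                                   / p.friction)
        self.origin = m.coords[system.steered].copy()
        self.work_spring = 0.0
        self.dissipation = 0.0
        self.t = 0.0

    def axis_pos(self, x: np.ndarray) -> float:
        return float((x - self.origin) @ self.sys.direction)

    def _break_springs(self):
        m = self.sys.model
        if not m.breakable.any():
            return
        i, j = m.springs[:, 0], m.springs[:, 1]
        L = np.linalg.norm(self.X[j] - self.X[i], axis=1)
        snap = (m.breakable & (self.alive > 0)
                & (L > self.sys.protocol.break_factor * m.rest_lengths))
        self.alive[snap] = 0.0

    def step(self, f_ext_steered: np.ndarray):
        """One overdamped Euler–Maruyama step with external steered force."""
        p = self.sys.protocol
        m = self.sys.model
        F = enm_forces(self.X, m.springs, m.rest_lengths, m.stiffness,
                       self.alive)
        F[self.sys.steered] += f_ext_steered
        noise = self.noise_sigma * self.rng.standard_normal(self.X.shape)
        dx = (p.dt_ns / p.friction) * F + noise
        dx[~self.mobile] = 0.0
        x_st_old = self.X[self.sys.steered].copy()
        self.X += dx
        self.work_spring += float(f_ext_steered
                                  @ (self.X[self.sys.steered] - x_st_old))
        self.dissipation += float(
            np.sum(dx[self.mobile] ** 2)) * p.friction / p.dt_ns
        self._break_springs()
        self.t += p.dt_ns


def run_ramp(system: ConfiguredSystem, rigid_steered: bool = False,
             stop_at_clamp_force: bool = True,
             x0: Optional[np.ndarray] = None
             ) -> Tuple[SMDResult, "_Engine"]:
    """Constant-velocity (force-ramp) pulling phase.

    The dummy point starts at the steered bead's t=0 position and moves
    at ``v_pull`` along the pulling direction; the applied force is the
    virtual-spring extension projected on that direction.  With
    ``rigid_steered`` the steered bead is immobilised (calibration mode:
    the force grows exactly as k·v·t).  Stops at the first crossing of
    the clamp setpoint when ``stop_at_clamp_force`` is set.
    """
    p = system.protocol
    eng = _Engine(system, x0=x0, rigid_steered=rigid_steered)
    n_steps = int(round(p.ramp_duration_ns / p.dt_ns))
    ts, fs, dpos, spos = [], [], [], []
    switch_time = None

    def record(t, f_pn, d, s):
        ts.append(t)
        fs.append(f_pn)
        dpos.append(d)
        spos.append(s)

    traj_frames = [eng.X.copy()]
    traj_times = [0.0]
    for step in range(n_steps):
        t = eng.t
        dummy = eng.axis_pos(eng.origin) + p.v_pull_a_ns * t
        ext = dummy - eng.axis_pos(eng.X[system.steered])
        f_kcal = eng.k_spring_kcal * ext
        f_pn = f_kcal * KCAL_PER_MOL_PER_A_TO_PN
        if step % p.sample_stride == 0:
            record(t, f_pn, dummy, eng.axis_pos(eng.X[system.steered]))
        if stop_at_clamp_force and f_pn >= p.clamp_force_pn:
            switch_time = t
            if step % p.sample_stride != 0:
                record(t, f_pn, dummy, eng.axis_pos(eng.X[system.steered]))
            break
        direction = system.direction
        if p.recompute_direction:
            anchor = eng.X[system.fixed].mean(axis=0)
            d = eng.X[system.steered] - anchor
            direction = d / np.linalg.norm(d)
        eng.step(f_kcal * direction)
        if (step + 1) % (p.sample_stride * 10) == 0:
            traj_frames.append(eng.X.copy())
            traj_times.append(eng.t)
    else:
        # ramp finished without reaching the setpoint
        t = eng.t
        dummy = p.v_pull_a_ns * t
        ext = dummy - eng.axis_pos(eng.X[system.steered])
        f_pn = eng.k_spring_kcal * ext * KCAL_PER_MOL_PER_A_TO_PN
        record(t, f_pn, dummy, eng.axis_pos(eng.X[system.steered]))

    if traj_times[-1] < eng.t:
        traj_frames.append(eng.X.copy())
        traj_times.append(eng.t)
    topo = system.model.atoms if system.model.atoms is not None else _bead_structure(system.model)
    traj = Trajectory(topo.copy(), np.array(traj_frames), np.array(traj_times))
    trace = ForceTrace(np.array(ts), np.array(fs), np.array(dpos),
                       np.array(spos), np.array(["ramp"] * len(ts), dtype=object))
    completed = switch_time is not None or not stop_at_clamp_force
    res = SMDResult(trajectory=traj, trace=trace, completed=completed,
                    switch_time_ns=switch_time,
                    work_spring_kcal=eng.work_spring,
                    dissipation_kcal=eng.dissipation,
                    broken_springs=int(np.sum(eng.alive == 0)))
    if stop_at_clamp_force and switch_time is None:
        warnings.warn("ramp ended before reaching the clamp setpoint "
                      "(protocol incomplete)", stacklevel=2)
    return res, eng


def run_clamp(system: ConfiguredSystem, engine: Optional[_Engine] = None,
              duration_ns: Optional[float] = None) -> Tuple[SMDResult, "_Engine"]:
    """Force-clamp phase: constant setpoint force on the steered bead.

    Continues from a ramp engine when given one, otherwise starts from
    the native geometry.  The applied-force channel is the setpoint by
    construction.
    """
    p = system.protocol
    eng = engine if engine is not None else _Engine(system)
    if duration_ns is None:
        duration_ns = p.clamp_duration_ns
    f_kcal = p.clamp_force_pn / KCAL_PER_MOL_PER_A_TO_PN
    f_ext = f_kcal * system.direction
    n_steps = int(round(duration_ns / p.dt_ns))
    t0 = eng.t
    ts, fs, dpos, spos = [], [], [], []
    traj_frames = [eng.X.copy()]
    traj_times = [eng.t]
    for step in range(n_steps):
        if step % p.sample_stride == 0:
            s = eng.axis_pos(eng.X[system.steered])
            ts.append(eng.t)
            fs.append(p.clamp_force_pn)
            dpos.append(s)   # dummy rides with the steered bead under clamp
            spos.append(s)
        eng.step(f_ext)
        if (step + 1) % (p.sample_stride * 10) == 0:
            traj_frames.append(eng.X.copy())
            traj_times.append(eng.t)
    if traj_times[-1] < eng.t:
        traj_frames.append(eng.X.copy())
        traj_times.append(eng.t)
    topo = system.model.atoms if system.model.atoms is not None else _bead_structure(system.model)
    traj = Trajectory(topo.copy(), np.array(traj_frames), np.array(traj_times))
    trace = ForceTrace(np.array(ts), np.array(fs), np.array(dpos),
                       np.array(spos),
                       np.array(["clamp"] * len(ts), dtype=object))
    res = SMDResult(trajectory=traj, trace=trace, completed=True,
                    switch_time_ns=t0,
                    work_spring_kcal=eng.work_spring,
                    dissipation_kcal=eng.dissipation,
                    broken_springs=int(np.sum(eng.alive == 0)))
    return res, eng


def run_ramp_clamp(system: ConfiguredSystem) -> SMDResult:
    """Full protocol: ramp until the 25 pN (setpoint) crossing, then clamp.

    If the ramp never reaches the setpoint the result is flagged
    ``completed=False`` and no clamp phase is run (protocol-incomplete
    signal, not an exception).
    """
    ramp_res, eng = run_ramp(system, stop_at_clamp_force=True)
    if ramp_res.switch_time_ns is None:
        return ramp_res
    clamp_res, eng = run_clamp(system, engine=eng)
    rt, ct = ramp_res.trace, clamp_res.trace
    # drop a duplicated boundary sample if times collide
    keep = ct.times > rt.times[-1]
    trace = ForceTrace(
        np.concatenate([rt.times, ct.times[keep]]),
        np.concatenate([rt.force, ct.force[keep]]),
        np.concatenate([rt.dummy_pos, ct.dummy_pos[keep]]),
        np.concatenate([rt.steered_pos, ct.steered_pos[keep]]),
        np.concatenate([rt.phase, ct.phase[keep]]),
    )
    tj_r, tj_c = ramp_res.trajectory, clamp_res.trajectory
    keep_f = tj_c.times > tj_r.times[-1]
    traj = Trajectory(tj_r.structure,
                      np.concatenate([tj_r.coords, tj_c.coords[keep_f]]),
                      np.concatenate([tj_r.times, tj_c.times[keep_f]]))
    return SMDResult(trajectory=traj, trace=trace, completed=True,
                     switch_time_ns=ramp_res.switch_time_ns,
                     work_spring_kcal=clamp_res.work_spring_kcal,
                     dissipation_kcal=clamp_res.dissipation_kcal,
                     broken_springs=clamp_res.broken_springs)


def _bead_structure(model: ENMModel) -> Structure:
    from .structures import Atom
    return Structure([
        Atom(i + 1, "CA", "C", "GLY", i + 1, "A", model.coords[i],
             mass=model.masses[i])
        for i in range(model.n_beads)
    ])


def rupture_force(trace: ForceTrace, smooth_window_ns: float = 0.0
                  ) -> RuptureResult:
    """Peak of the (smoothed) ramp-phase force–time curve.

    A running mean of width ``smooth_window_ns`` is applied first; the
    rupture force is the global maximum of the smoothed ramp-phase trace
    and the rupture time its location.
    """
    mask = trace.ramp_mask
    if not mask.any():
        raise ConfigurationError("trace has no ramp-phase samples")
    t = trace.times[mask]
    f = trace.force[mask]
    if len(t) > 1:
        dt = np.median(np.diff(t))
        n_win = max(1, int(round(smooth_window_ns / dt))) if smooth_window_ns > 0 else 1
    else:
        n_win = 1
    sm = uniform_filter1d(f, size=n_win, mode="nearest") if n_win > 1 else f.copy()
    if np.allclose(sm, sm[0]):
        warnings.warn("force trace is constant; rupture force is degenerate",
                      stacklevel=2)
        return RuptureResult(float(sm[0]), float(t[0]), sm)
    k = int(np.argmax(sm))
    return RuptureResult(float(sm[k]), float(t[k]), sm)
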