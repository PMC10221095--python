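"""Orchestration: replicate statistics, end-to-end analysis, SMD experiments.

The pipeline mirrors a steered-dynamics study design: three seeded
replicate runs per condition, every metric aggregated as mean ± SD over
runs, and two-sample comparisons between conditions (Welch's t by
default).  ``make_fixtures`` writes a complete synthetic input set with
ground-truth sidecars; ``analyze_trajectory`` turns trajectories into
tidy metric tables, an occupancy table, dissociation estimates and
binding-energy series; ``smd_experiment`` runs seeded replicate pulling
simulations and tabulates rupture forces.
"""

from __future__ import annotations

import hashlib
import json
import os
import warnings
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import yaml

from . import geometry, hbonds, sasa as sasa_mod
from .energetics import ParameterTable, binding_energy
from .errors import EmptyInputError, InsufficientReplicatesError, RampClampError
from .smd import (
    LoadingProtocol,
    build_enm,
    rupture_force,
    run_ramp,
    run_ramp_clamp,
    set_loading,
)
from .structures import (
    Structure,
    Trajectory,
    read_pdb,
    read_xyz_traj,
    write_force_trace,
    write_pdb,
    write_xyz_traj,
)
from .synthetic import (
    GT_INTERFACE_PAIRS,
    WT_INTERFACE_PAIRS,
    InterfaceSpec,
    build_complex,
    jitter_trajectory,
)

__version__ = "0.1.0"


# ------------------------------------------------------------- statistics

@dataclass
class ReplicateSummary:
    """Mean ± SD of one metric over replicate runs."""

    metric: str
    condition: str
    values: List[float]
    mean: float
    sd: float
    n: int


def aggregate(per_run_values: Sequence[float], metric: str = "",
              condition: str = "") -> ReplicateSummary:
    """Sample mean and sample SD (n−1 denominator) over replicate runs."""
    vals = [float(v) for v in per_run_values]
    if len(vals) == 0:
        raise EmptyInputError("aggregate needs at least one value")
    arr = np.asarray(vals)
    if len(vals) == 1:
        warnings.warn("single replicate: SD reported as 0 by convention",
                      stacklevel=2)
        sd = 0.0
    else:
        sd = float(arr.std(ddof=1))
    return ReplicateSummary(metric=metric, condition=condition, values=vals,
                            mean=float(arr.mean()), sd=sd, n=len(vals))


def star_code(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_conditions(summary_a: ReplicateSummary, summary_b: ReplicateSummary,
                       test: str = "welch"):
    """Two-tailed two-sample comparison of replicate summaries.

    Returns ``(p_value, stars)``.  ``test`` is ``"welch"`` (unequal
    variances, default) or ``"student"`` (pooled).
    """
    a = np.asarray(summary_a.values, dtype=float)
    b = np.asarray(summary_b.values, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientReplicatesError("need ≥2 replicates per condition")
    if test not in ("welch", "student"):
        raise RampClampError(f"unknown test {test!r}")
    with np.errstate(all="ignore"):
        res = stats.ttest_ind(a, b, equal_var=(test == "student"))
    p = float(res.pvalue)
    if np.isnan(p):
        p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return p, star_code(p)


# ------------------------------------------------------------------ config

@dataclass
class RunConfig:
    """Declarative configuration for the synthetic analysis pipeline."""

    outdir: str = "rampclamp_out"
    condition: str = "WT"             # WT or GT interface occupancies
    chain_set_a: List[str] = field(default_factory=lambda: ["A"])
    chain_set_b: List[str] = field(default_factory=lambda: ["B"])
    seeds: List[int] = field(default_factory=lambda: [1, 2, 3])
    n_frames: int = 400
    frame_dt: float = 0.02            # ns between frames
    temporal_model: str = "iid"
    p_stay: float = 0.0
    d_cut: float = 3.5
    ang_cut: float = 30.0
    sasa_probe: float = 1.4
    sasa_n_points: int = 240
    sasa_stride: int = 100
    energy_stride: int = 100
    cd_loop: str = "name CA and chain B and resseq 50-60"
    de_loop: str = "name CA and chain B and resseq 62-98"
    c_strand: str = "name CA and chain B"
    g_strand: str = "name CA and chain A"
    alpha_atom_a: str = "name CA and chain B and resseq 52"
    alpha_atom_b: str = "name CA and chain B and resseq 53"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise RampClampError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @property
    def interface_spec(self) -> InterfaceSpec:
        pairs = WT_INTERFACE_PAIRS if self.condition == "WT" else GT_INTERFACE_PAIRS
        return InterfaceSpec(pairs=list(pairs), temporal_model=self.temporal_model,
                             p_stay=self.p_stay)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _synthetic_parameter_table(structure: Structure) -> ParameterTable:
    """Complete per-atom parameters for a synthetic complex.

    Charges make the interface mildly attractive (donor side positive,
    acceptor side negative); Born radii and LJ terms are element-typical.
    """
    by_elem = {
        "O": (-0.50, 0.12, 1.70, 1.50),
        "N": (0.30, 0.20, 1.85, 1.55),
        "H": (0.20, 0.046, 0.22, 1.20),
        "C": (0.00, 0.07, 2.00, 1.70),
    }
    entries = {}
    for a in structure.atoms:
        entries[(a.res_name, a.name)] = by_elem.get(a.element, by_elem["C"])
    return ParameterTable(entries)


# ------------------------------------------------------------- fixtures

def make_fixtures(config: RunConfig, outdir: Optional[str] = None) -> dict:
    """Generate the full synthetic input set with ground-truth sidecars.

    Writes ``complex.pdb``, one XYZ trajectory and one presence-matrix
    CSV per seed, an energetics parameter file, the config, and a
    manifest.  Returns the manifest dict.
    """
    outdir = outdir or config.outdir
    os.makedirs(outdir, exist_ok=True)
    spec = config.interface_spec
    cplx, gt = build_complex(spec, seed=config.seeds[0])
    write_pdb(cplx, os.path.join(outdir, "complex.pdb"))
    pd.DataFrame({
        "pair": [f"{a}-{b}" for a, b in gt.pair_labels],
        "donor_index": gt.donor_indices,
        "hydrogen_index": gt.hydrogen_indices,
        "acceptor_index": gt.acceptor_indices,
        "occupancy_target": gt.occupancy_targets,
    }).to_csv(os.path.join(outdir, "interface_ground_truth.csv"), index=False)
    for seed in config.seeds:
        traj, truth = jitter_trajectory(cplx, gt, spec, config.n_frames,
                                        seed=seed, frame_dt=config.frame_dt)
        write_xyz_traj(traj, os.path.join(outdir, f"traj_run{seed}.xyz"))
        pres = pd.DataFrame(
            truth.presence.astype(int),
            columns=[f"{a}-{b}" for a, b in gt.pair_labels],
        )
        pres.to_csv(os.path.join(outdir, f"presence_run{seed}.csv"), index=False)
    _synthetic_parameter_table(cplx).to_file(os.path.join(outdir, "params.dat"))
    config.to_yaml(os.path.join(outdir, "config.yaml"))
    manifest = {
        "config_hash": config.config_hash(),
        "seeds": list(config.seeds),
        "condition": config.condition,
        "n_frames": config.n_frames,
        "version": __version__,
        "files": sorted(os.listdir(outdir)),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# -------------------------------------------------------------- analysis

def _load_or_generate(config: RunConfig, fixtures_dir: Optional[str]):
    spec = config.interface_spec
    if fixtures_dir and os.path.exists(os.path.join(fixtures_dir, "complex.pdb")):
        cplx = read_pdb(os.path.join(fixtures_dir, "complex.pdb"))
        trajs = []
        for seed in config.seeds:
            path = os.path.join(fixtures_dir, f"traj_run{seed}.xyz")
            trajs.append(read_xyz_traj(path, cplx))
        params_path = os.path.join(fixtures_dir, "params.dat")
        table = (ParameterTable.from_file(params_path)
                 if os.path.exists(params_path)
                 else _synthetic_parameter_table(cplx))
        return cplx, trajs, table
    cplx, gt = build_complex(spec, seed=config.seeds[0])
    trajs = [jitter_trajectory(cplx, gt, spec, config.n_frames, seed=s,
                               frame_dt=config.frame_dt)[0]
             for s in config.seeds]
    return cplx, trajs, _synthetic_parameter_table(cplx)


def analyze_trajectory(config: RunConfig, fixtures_dir: Optional[str] = None,
                       write: bool = True) -> dict:
    """Run the full per-trajectory analysis for every replicate.

    Returns a report bundle: tidy per-frame metric table, Table-1-style
    occupancy table, dissociation estimates, replicate summaries, and a
    manifest.  With ``write=True`` everything lands in ``config.outdir``
    as CSV/JSON.
    """
    cplx, trajs, param_table = _load_or_generate(config, fixtures_dir)
    chain_a, chain_b = set(config.chain_set_a), set(config.chain_set_b)
    donors = hbonds.find_donors(cplx)
    acceptors = hbonds.find_acceptors(cplx)
    ca_sel = cplx.select("name CA")
    metric_rows = []
    run_occ: List[Dict] = []
    nhb_means, fd_emp, fd_ind = [], [], []
    rgyr_means, rmsd_finals, h_means = [], [], []
    alpha_means, theta_means = [], []
    bsasa_means, eb_means = [], []
    warn_header: List[str] = []

    def tidy(run, metric, t, v):
        for ti, vi in zip(np.atleast_1d(t), np.atleast_1d(v)):
            metric_rows.append({"run": run, "time_ns": float(ti),
                                "metric": metric, "value": float(vi)})

    for seed, traj in zip(config.seeds, trajs):
        frames_bonds = hbonds.detect_trajectory(traj, donors, acceptors,
                                                config.d_cut, config.ang_cut)
        inter = hbonds.interfacial_filter(frames_bonds, chain_a, chain_b)
        nhb = hbonds.nhb_series(inter)
        occ = hbonds.occupancies(inter, chain_a)
        run_occ.append(occ)
        nhb_means.append(float(nhb.mean()))
        fd_emp.append(hbonds.dissociation_probability(
            nhb_per_frame=nhb, method="empirical_all_broken").probability)
        fd_ind.append(hbonds.dissociation_probability(
            occupancy_values=list(occ.values()),
            method="independence_product").probability)
        tidy(seed, "nhb", traj.times, nhb)

        rmsd = geometry.rmsd_series(traj, ca_sel, ref_frame=0)
        rg = geometry.rgyr_series(traj)
        tidy(seed, "rmsd_ca", traj.times, rmsd)
        tidy(seed, "rgyr", traj.times, rg)
        rmsd_finals.append(float(rmsd[-1]))
        rgyr_means.append(float(rg.mean()))

        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            cd = cplx.select(config.cd_loop)
            de = cplx.select(config.de_loop)
            cs = cplx.select(config.c_strand)
            gs = cplx.select(config.g_strand)
            aa = cplx.select(config.alpha_atom_a)
            ab = cplx.select(config.alpha_atom_b)
            for w in wlist:
                warn_header.append(str(w.message))
        if cd.size and de.size:
            h = geometry.metric_H(traj, cd, de)
            tidy(seed, "H", traj.times, h)
            h_means.append(float(h.mean()))
        if cs.size >= 3 and aa.size and ab.size:
            al = geometry.metric_alpha(traj, cs, int(aa[0]), int(ab[0]))
            tidy(seed, "alpha", traj.times, al)
            alpha_means.append(float(al.mean()))
        if cs.size >= 3 and gs.size >= 3:
            th = geometry.metric_theta(traj, gs, cs)
            tidy(seed, "theta", traj.times, th)
            theta_means.append(float(th.mean()))

        s_stride = max(1, config.sasa_stride)
        bvals = []
        for f in range(0, traj.n_frames, s_stride):
            frame = traj.frame(f)
            bvals.append(sasa_mod.buried_sasa(frame, chain_a, chain_b,
                                              probe=config.sasa_probe,
                                              n_points=config.sasa_n_points))
        tidy(seed, "buried_sasa_nm2", traj.times[::s_stride], bvals)
        bsasa_means.append(float(np.mean(bvals)))

        e_stride = max(1, config.energy_stride)
        _, eb = binding_energy(traj, chain_a, chain_b, param_table,
                               stride=e_stride,
                               n_sphere_points=config.sasa_n_points)
        tidy(seed, "e_binding", traj.times[::e_stride], eb)
        eb_means.append(float(eb.mean()))

    spec = config.interface_spec
    ch_a, ch_b = config.chain_set_a[0], config.chain_set_b[0]
    expected_pairs = [
        ((ch_a, ra, sa), (ch_b, rb, sb)) for (ra, sa), (rb, sb), _ in spec.pairs
    ]
    occ_table = hbonds.occupancy_table(run_occ, expected_pairs=expected_pairs)
    occ_table.insert(0, "condition", config.condition)
    summaries = [
        aggregate(nhb_means, "nhb", config.condition),
        aggregate(fd_ind, "f_D_independence", config.condition),
        aggregate(fd_emp, "f_D_empirical", config.condition),
        aggregate(rgyr_means, "rgyr", config.condition),
        aggregate(bsasa_means, "buried_sasa_nm2", config.condition),
        aggregate(eb_means, "e_binding", config.condition),
    ]
    for name, vals in [("H", h_means), ("alpha", alpha_means),
                       ("theta", theta_means)]:
        if vals:
            summaries.append(aggregate(vals, name, config.condition))
    summary_df = pd.DataFrame([asdict(s) for s in summaries])
    summary_df["values"] = summary_df["values"].map(
        lambda v: ";".join(f"{x:.10g}" for x in v))
    metrics_df = pd.DataFrame(metric_rows)
    manifest = {
        "config_hash": config.config_hash(),
        "seeds": list(config.seeds),
        "condition": config.condition,
        "version": __version__,
        "n_frames": int(trajs[0].n_frames),
        "warnings": sorted(set(warn_header)),
        "hbond_mode": "angle",
    }
    bundle = {
        "metrics": metrics_df,
        "occupancy_table": occ_table,
        "summaries": summary_df,
        "manifest": manifest,
        "per_run_occupancies": run_occ,
    }
    if write:
        os.makedirs(config.outdir, exist_ok=True)
        metrics_df.to_csv(os.path.join(config.outdir, "metrics.csv"),
                          index=False)
        occ_table.to_csv(os.path.join(config.outdir, "occupancy_table.csv"),
                         index=False)
        summary_df.to_csv(os.path.join(config.outdir, "summaries.csv"),
                          index=False)
        with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return bundle


# ---------------------------------------------------------- SMD pipeline

@dataclass
class SMDConfig:
    """Configuration of a replicate pulling experiment on a toy complex."""

    outdir: str = "smd_out"
    modes: List[int] = field(default_factory=lambda: [1, 2])
    seeds: List[int] = field(default_factory=lambda: [1, 2, 3])
    n_interface_bonds: int = 4
    k_enm: float = 1.0
    k_interface: float = 0.1
    enm_cutoff: float = 10.0
    k_spring_pn_nm: float = 34.74
    v_pull_a_ns: float = 5.0
    clamp_force_pn: float = 25.0
    temperature_k: float = 300.0
    ramp_duration_ns: float = 3.0
    clamp_duration_ns: float = 1.0
    dt_ns: float = 2.0e-5
    smooth_window_ns: float = 0.02
    run_clamp_phase: bool = True

    @classmethod
    def from_yaml(cls, path) -> "SMDConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise RampClampError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _smd_fixture(config: SMDConfig) -> Structure:
    """Small two-chain Cα complex for pulling experiments."""
    spec = InterfaceSpec(pairs=WT_INTERFACE_PAIRS[:config.n_interface_bonds])
    cplx, _ = build_complex(spec, seed=0)
    ca = cplx.select("name CA")
    return cplx.subset(ca)


def _anchors_for_mode(structure: Structure, mode: int):
    """VAL115-like / CYS15-like anchor choice on chain A; steered bead is
    the chain-B C-terminal Cα."""
    chains = [a.chain_id for a in structure.atoms]
    a_idx = [i for i, c in enumerate(chains) if c == "A"]
    b_idx = [i for i, c in enumerate(chains) if c == "B"]
    steered = b_idx[-1]
    if mode == 1:
        return [a_idx[-1]], steered
    return [a_idx[0], a_idx[-1]], steered


def smd_experiment(config: SMDConfig, write: bool = True) -> dict:
    """Seeded replicate pulling runs per loading mode.

    Ramp runs measure rupture force; when ``run_clamp_phase`` is set a
    ramp→clamp protocol run per seed records the 25 pN switch.  Runs that
    never reach the clamp setpoint are flagged in the manifest rather
    than raised.
    """
    structure = _smd_fixture(config)
    rows = []
    incomplete = []
    traces = {}
    for mode in config.modes:
        fixed, steered = _anchors_for_mode(structure, mode)
        for seed in config.seeds:
            protocol = LoadingProtocol(
                mode=mode, k_spring_pn_nm=config.k_spring_pn_nm,
                v_pull_a_ns=config.v_pull_a_ns,
                clamp_force_pn=config.clamp_force_pn,
                temperature_k=config.temperature_k,
                dt_ns=config.dt_ns,
                ramp_duration_ns=config.ramp_duration_ns,
                clamp_duration_ns=config.clamp_duration_ns,
                seed=seed,
            )
            model = build_enm(structure, cutoff=config.enm_cutoff,
                              k_enm=config.k_enm,
                              k_interface=config.k_interface)
            system = set_loading(model, protocol, fixed, steered)
            res, _ = run_ramp(system, stop_at_clamp_force=False)
            rup = rupture_force(res.trace, config.smooth_window_ns)
            rows.append({
                "mode": mode, "seed": seed,
                "rupture_force_pN": rup.rupture_force,
                "rupture_time_ns": rup.rupture_time,
                "broken_springs": res.broken_springs,
            })
            traces[(mode, seed, "ramp")] = res.trace
            if config.run_clamp_phase:
                model2 = build_enm(structure, cutoff=config.enm_cutoff,
                                   k_enm=config.k_enm,
                                   k_interface=config.k_interface)
                system2 = set_loading(model2, protocol, fixed, steered)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rc = run_ramp_clamp(system2)
                traces[(mode, seed, "ramp_clamp")] = rc.trace
                if not rc.completed:
                    incomplete.append({"mode": mode, "seed": seed})
                else:
                    rows[-1]["clamp_switch_time_ns"] = rc.switch_time_ns
                    clamp_f = rc.trace.force[rc.trace.clamp_mask]
                    rows[-1]["clamp_mean_force_pN"] = float(clamp_f.mean())
    rupture_df = pd.DataFrame(rows)
    mode_summaries = [
        aggregate(rupture_df[rupture_df["mode"] == m]["rupture_force_pN"],
                  "rupture_force_pN", f"mode{m}")
        for m in config.modes
    ]
    manifest = {
        "version": __version__,
        "seeds": list(config.seeds),
        "modes": list(config.modes),
        "clamp_force_pn": config.clamp_force_pn,
        "incomplete_runs": incomplete,
        "replicates_per_condition": len(config.seeds),
    }
    bundle = {"rupture_table": rupture_df, "mode_summaries": mode_summaries,
              "manifest": manifest, "traces": traces}
    if write:
        os.makedirs(config.outdir, exist_ok=True)
        rupture_df.to_csv(os.path.join(config.outdir, "rupture_table.csv"),
                          index=False)
        pd.DataFrame([asdict(s) for s in mode_summaries]).assign(
            values=lambda d: d["values"].map(
                lambda v: ";".join(f"{x:.10g}" for x in v))
        ).to_csv(os.path.join(config.outdir, "rupture_summary.csv"), index=False)
        for (mode, seed, kind), tr in traces.items():
            write_force_trace(tr, os.path.join(
                config.outdir, f"trace_mode{mode}_seed{seed}_{kind}.csv"))
        with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return bundle
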