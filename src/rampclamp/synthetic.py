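"""Seeded generators for every input class the analysis consumes.

All generators are pure functions of (specification, seed) and come with
machine-readable ground truth, so estimator tests can compare against
known targets:

* :func:`build_strand` — ideal β-strand-like Cα traces with a known axis;
* :func:`build_complex` — a two-chain complex whose interface realises a
  prescribed set of donor–hydrogen–acceptor bonds (inside the detection
  cutoffs) plus decoys placed outside them;
* :func:`jitter_trajectory` — trajectories in which each interfacial bond
  is present with a prescribed occupancy, independently per frame or with
  Markov (persistent) dynamics;
* :func:`make_force_trace` — ramp/peak and ramp/plateau force traces with
  known peak values.

The default interface emulates the twelve residue pairs of the
CD47/CD172a binding site, with wild-type occupancies (e.g. 0.82 for
GLU35–ARG69, 0.52 for PCA1–SER66).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import EmptyInputError, GenerationError, RampClampError
from .structures import Atom, ForceTrace, Structure, Trajectory

#: CD47/CD172a-style interface: (CD47 residue, CD172a residue, occupancy).
#: Residue numbering and occupancies follow the reported free-dynamics
#: survival ratios for the wild-type (pyroglutamate) complex.
WT_INTERFACE_PAIRS: List[Tuple[Tuple[str, int], Tuple[str, int], float]] = [
    (("GLU", 106), ("LYS", 53), 0.54),
    (("GLU", 104), ("LYS", 96), 0.66),
    (("GLU", 104), ("GLN", 52), 0.60),
    (("GLU", 100), ("ARG", 69), 0.79),
    (("GLU", 97), ("LYS", 96), 0.66),
    (("GLU", 97), ("LYS", 53), 0.34),
    (("ASP", 51), ("ARG", 95), 0.07),
    (("ASP", 46), ("SER", 98), 0.53),
    (("GLU", 35), ("ARG", 69), 0.82),
    (("PCA", 1), ("SER", 66), 0.52),
    (("PCA", 1), ("GLU", 54), 0.00),
    (("PCA", 1), ("GLN", 52), 0.00),
]

#: Same interface for the unmodified (N-terminal glutamine) complex.
GT_INTERFACE_PAIRS: List[Tuple[Tuple[str, int], Tuple[str, int], float]] = [
    (("GLU", 106), ("LYS", 53), 0.48),
    (("GLU", 104), ("LYS", 96), 0.52),
    (("GLU", 104), ("GLN", 52), 0.22),
    (("GLU", 100), ("ARG", 69), 0.69),
    (("GLU", 97), ("LYS", 96), 0.30),
    (("GLU", 97), ("LYS", 53), 0.28),
    (("ASP", 51), ("ARG", 95), 0.77),
    (("ASP", 46), ("SER", 98), 0.30),
    (("GLU", 35), ("ARG", 69), 0.81),
    (("GLN", 1), ("SER", 66), 0.21),
    (("GLN", 1), ("GLU", 54), 0.08),
    (("GLN", 1), ("GLN", 52), 0.15),
]

DEFAULT_INTERFACE_PAIRS = WT_INTERFACE_PAIRS


@dataclass
class InterfaceSpec:
    """Prescription for a synthetic two-chain interface.

    ``pairs`` lists ((res_name_a, res_seq_a), (res_name_b, res_seq_b),
    occupancy); chain A holds the acceptor (carboxylate-like O), chain B
    the donor (N with an explicit hydrogen).  ``temporal_model`` is
    ``"iid"`` or ``"markov"``; for the latter ``p_stay`` is the lag-1
    autocorrelation of the presence sequence (stationary occupancy stays
    at the target).
    """

    pairs: List[Tuple[Tuple[str, int], Tuple[str, int], float]] = field(
        default_factory=lambda: list(DEFAULT_INTERFACE_PAIRS))
    temporal_model: str = "iid"
    p_stay: float = 0.0
    chain_a: str = "A"
    chain_b: str = "B"
    n_decoys: int = 3
    spacing: float = 8.0          # Å between bond units
    d_on: float = 2.9             # donor–acceptor distance when present
    d_off_shift: float = 1.5      # radial acceptor shift when absent
    deviation_deg: float = 5.0    # D–H···A deviation from linear

    def __post_init__(self):
        for (_, _, occ) in self.pairs:
            if not 0.0 <= occ <= 1.0:
                raise RampClampError("occupancy targets must lie in [0, 1]")
        if self.temporal_model not in ("iid", "markov"):
            raise RampClampError("temporal_model must be 'iid' or 'markov'")
        if not 0.0 <= self.p_stay < 1.0:
            raise RampClampError("p_stay must lie in [0, 1)")

    @property
    def n_bonds(self) -> int:
        return len(self.pairs)

    @property
    def occupancies(self) -> np.ndarray:
        return np.array([occ for _, _, occ in self.pairs])


@dataclass
class ComplexGroundTruth:
    """Sidecar truth for a generated complex."""

    donor_indices: np.ndarray     # N of each bond (chain B)
    hydrogen_indices: np.ndarray
    acceptor_indices: np.ndarray  # O of each bond (chain A)
    pair_labels: List[Tuple[str, str]]
    occupancy_targets: np.ndarray


@dataclass
class TrajectoryGroundTruth:
    presence: np.ndarray          # (n_frames, n_bonds) bool
    occupancy_targets: np.ndarray
    realized_occupancy: np.ndarray


@dataclass
class ForceTraceGroundTruth:
    peak_pn: float
    peak_time_ns: float
    plateau_pn: Optional[float] = None


# ------------------------------------------------------------------ strands

def build_strand(n_res: int, rise: float = 3.3, direction=(0.0, 0.0, 1.0),
                 origin=(0.0, 0.0, 0.0), chain_id: str = "A",
                 start_resseq: int = 1, pleat_amplitude: float = 0.0,
                 serial_start: int = 1) -> Structure:
    """An ideal β-strand-like Cα trace along ``direction``.

    Residues are placed every ``rise`` Å; an optional alternating
    transverse pleat of the given amplitude mimics the Cα zigzag of real
    strands.  The ground-truth axis is ``direction`` (exactly, when the
    pleat is zero).
    """
    if n_res < 3:
        raise RampClampError("a strand needs at least 3 residues")
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    o = np.asarray(origin, dtype=float)
    # transverse unit vector for the pleat
    probe = np.array([1.0, 0.0, 0.0])
    if abs(d @ probe) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    w = np.cross(d, probe)
    w /= np.linalg.norm(w)
    atoms = []
    for i in range(n_res):
        pos = o + i * rise * d + ((-1) ** i) * pleat_amplitude * w
        atoms.append(Atom(serial_start + i, "CA", "C", "GLY",
                          start_resseq + i, chain_id, pos))
    return Structure(atoms)


# ------------------------------------------------------------------ complex

def _place_hydrogen(xn: np.ndarray, xa: np.ndarray, deviation_deg: float,
                    bond_length: float = 1.0) -> np.ndarray:
    """Place H on the N→A axis, tilted so D–H···A deviates as prescribed."""
    u = xa - xn
    u = u / np.linalg.norm(u)
    probe = np.array([1.0, 0.0, 0.0])
    if abs(u @ probe) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    w = np.cross(u, probe)
    w /= np.linalg.norm(w)

    def deviation(phi: float) -> float:
        xh = xn + bond_length * (np.cos(phi) * u + np.sin(phi) * w)
        a = xn - xh
        b = xa - xh
        c = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        return 180.0 - np.degrees(np.arccos(np.clip(c, -1, 1)))

    if deviation_deg <= 0:
        return xn + bond_length * u
    lo, hi = 0.0, np.pi / 3
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if deviation(mid) < deviation_deg:
            lo = mid
        else:
            hi = mid
    phi = 0.5 * (lo + hi)
    return xn + bond_length * (np.cos(phi) * u + np.sin(phi) * w)


def build_complex(spec: InterfaceSpec, seed: int = 0,
                  max_attempts: int = 5) -> Tuple[Structure, ComplexGroundTruth]:
    """Build a two-chain complex realising the prescribed interface.

    Each bond unit carries, on chain A, a Cα and a carboxylate-like
    acceptor O; on chain B, a Cα, a donor N and its explicit hydrogen.
    Bonds sit inside the detection cutoffs (D–A 2.9 Å, 5° deviation);
    decoy donor/acceptor pairs are placed outside them (distance or angle
    failures), and one intra-chain bond exercises the interfacial filter.
    """
    for attempt in range(max_attempts):
        atoms: List[Atom] = []
        serial = 1
        seen_res: dict = {}

        def add(name, element, res_name, res_seq, chain, pos) -> int:
            nonlocal serial
            atoms.append(Atom(serial, name, element, res_name, res_seq,
                              chain, np.asarray(pos, dtype=float)))
            serial += 1
            return len(atoms) - 1

        def occurrence(res_key) -> int:
            seen_res[res_key] = seen_res.get(res_key, 0) + 1
            return seen_res[res_key]

        don_idx, hyd_idx, acc_idx, labels = [], [], [], []
        for k, ((res_a, seq_a), (res_b, seq_b), occ) in enumerate(spec.pairs):
            x0 = k * spec.spacing
            xa = np.array([x0, 0.0, 0.0])                   # acceptor O
            xn = np.array([x0, 0.0, spec.d_on])             # donor N
            xh = _place_hydrogen(xn, xa, spec.deviation_deg)
            # shared residues keep unique atom names per occurrence
            occ_a = occurrence((spec.chain_a, seq_a))
            occ_b = occurrence((spec.chain_b, seq_b))
            if occ_a == 1:
                add("CA", "C", res_a, seq_a, spec.chain_a,
                    xa + np.array([0.0, -2.5, -2.0]))
            acc_idx.append(add(f"OE{occ_a}", "O", res_a, seq_a, spec.chain_a, xa))
            if occ_b == 1:
                add("CA", "C", res_b, seq_b, spec.chain_b,
                    xn + np.array([0.0, 2.5, 2.0]))
            don_idx.append(add(f"NZ{occ_b}", "N", res_b, seq_b, spec.chain_b, xn))
            hyd_idx.append(add(f"HZ{occ_b}", "H", res_b, seq_b, spec.chain_b, xh))
            labels.append((f"{res_a}{seq_a}", f"{res_b}{seq_b}"))
        base_x = spec.n_bonds * spec.spacing
        # distance-fail decoys: cross-chain D–A at 6 Å
        for k in range(spec.n_decoys):
            x0 = base_x + k * spec.spacing
            xa = np.array([x0, 0.0, 0.0])
            xn = np.array([x0, 0.0, 6.0])
            add("OD1", "O", "ASP", 200 + k, spec.chain_a, xa)
            add("ND2", "N", "ASN", 200 + k, spec.chain_b, xn)
            add("HD21", "H", "ASN", 200 + k, spec.chain_b,
                _place_hydrogen(xn, xa, 0.0))
        # angle-fail decoy: in-range distance, 60° deviation
        x0 = base_x + spec.n_decoys * spec.spacing
        xa = np.array([x0, 0.0, 0.0])
        xn = np.array([x0, 0.0, 3.4])
        add("OG", "O", "SER", 250, spec.chain_a, xa)
        add("N", "N", "GLY", 250, spec.chain_b, xn)
        add("H", "H", "GLY", 250, spec.chain_b, _place_hydrogen(xn, xa, 60.0))
        # intra-chain bond (chain B): inside cutoffs, must be filtered out
        x0 += spec.spacing
        xa = np.array([x0, 2.0, 4.0])
        xn = np.array([x0, 2.0, 4.0 + spec.d_on])
        add("O", "O", "ALA", 260, spec.chain_b, xa)
        add("N", "N", "ALA", 261, spec.chain_b, xn)
        add("H", "H", "ALA", 261, spec.chain_b, _place_hydrogen(xn, xa, 0.0))

        s = Structure(atoms)
        if _min_nonbonded_distance(s, hyd_idx, don_idx) >= 1.5:
            gt = ComplexGroundTruth(
                donor_indices=np.array(don_idx),
                hydrogen_indices=np.array(hyd_idx),
                acceptor_indices=np.array(acc_idx),
                pair_labels=labels,
                occupancy_targets=spec.occupancies,
            )
            return s, gt
    raise GenerationError(f"could not build a clash-free complex in "
                          f"{max_attempts} attempts")


def _min_nonbonded_distance(s: Structure, hyd_idx, don_idx) -> float:
    """Minimum distance over pairs that are not covalent N–H partners."""
    from scipy.spatial.distance import pdist, squareform

    X = s.coords
    D = squareform(pdist(X))
    np.fill_diagonal(D, np.inf)
    for h, d in zip(hyd_idx, don_idx):
        D[h, d] = D[d, h] = np.inf
    # any H within 1.2 Å of its own N is covalent; exclude all N–H pairs
    for i, a in enumerate(s.atoms):
        for j, b in enumerate(s.atoms):
            if {a.element, b.element} == {"N", "H"} and D[i, j] < 1.2:
                D[i, j] = D[j, i] = np.inf
    return float(D.min())


# --------------------------------------------------------------- trajectory

def _presence_sequences(spec: InterfaceSpec, n_frames: int,
                        rng: np.random.Generator) -> np.ndarray:
    occ = spec.occupancies
    n_bonds = spec.n_bonds
    pres = np.zeros((n_frames, n_bonds), dtype=bool)
    if spec.temporal_model == "iid":
        pres = rng.random((n_frames, n_bonds)) < occ[None, :]
    else:
        lam = spec.p_stay
        p_on_on = occ + (1.0 - occ) * lam
        p_off_on = occ * (1.0 - lam)
        state = rng.random(n_bonds) < occ
        pres[0] = state
        for f in range(1, n_frames):
            u = rng.random(n_bonds)
            state = np.where(state, u < p_on_on, u < p_off_on)
            pres[f] = state
    return pres


def jitter_trajectory(complex_structure: Structure, gt: ComplexGroundTruth,
                      spec: InterfaceSpec, n_frames: int, seed: int = 0,
                      frame_dt: float = 0.02
                      ) -> Tuple[Trajectory, TrajectoryGroundTruth]:
    """Toggle each bond per frame according to its temporal model.

    A bond is switched off by moving its acceptor radially away from the
    donor by ``d_off_shift`` Å (2.9 → 4.4 Å, unambiguously outside the
    3.5 Å cutoff); switched on, it sits at the native in-cutoff geometry.
    The realised presence matrix is returned as ground truth.
    """
    if n_frames < 1:
        raise EmptyInputError("n_frames must be ≥ 1")
    rng = np.random.default_rng(seed)
    pres = _presence_sequences(spec, n_frames, rng)
    X0 = complex_structure.coords
    coords = np.repeat(X0[None, :, :], n_frames, axis=0)
    for b in range(spec.n_bonds):
        a_i = gt.acceptor_indices[b]
        d_i = gt.donor_indices[b]
        u = X0[a_i] - X0[d_i]
        u = u / np.linalg.norm(u)
        off_pos = X0[a_i] + spec.d_off_shift * u
        off_frames = ~pres[:, b]
        coords[off_frames, a_i, :] = off_pos
    times = np.arange(n_frames, dtype=float) * frame_dt
    traj = Trajectory(complex_structure, coords, times)
    truth = TrajectoryGroundTruth(
        presence=pres,
        occupancy_targets=spec.occupancies,
        realized_occupancy=pres.mean(axis=0),
    )
    return traj, truth


# -------------------------------------------------------------- force traces

def make_force_trace(peak_pn: float, noise_sd: float = 0.0,
                     shape: str = "triangle", seed: int = 0,
                     n_samples: int = 1000, dt_ns: float = 0.01,
                     plateau_pn: Optional[float] = None,
                     ) -> Tuple[ForceTrace, ForceTraceGroundTruth]:
    """Synthesise a pulling force trace with known ground truth.

    ``"triangle"``: linear rise to ``peak_pn`` at mid-trace then linear
    fall (all ramp phase).  ``"ramp_plateau"``: linear rise to the peak,
    then a clamp-phase plateau at ``plateau_pn`` (default 25 pN).
    """
    if peak_pn <= 0:
        raise RampClampError("peak force must be positive")
    if n_samples < 2:
        raise EmptyInputError("a force trace needs at least 2 samples")
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples, dtype=float) * dt_ns
    if shape == "triangle":
        mid = n_samples // 2
        f = np.empty(n_samples)
        f[:mid + 1] = np.linspace(0.0, peak_pn, mid + 1)
        f[mid:] = np.linspace(peak_pn, 0.0, n_samples - mid)
        phase = np.array(["ramp"] * n_samples, dtype=object)
        truth = ForceTraceGroundTruth(peak_pn=peak_pn, peak_time_ns=t[mid])
    elif shape == "ramp_plateau":
        if plateau_pn is None:
            plateau_pn = 25.0
        mid = n_samples // 3
        f = np.empty(n_samples)
        f[:mid + 1] = np.linspace(0.0, peak_pn, mid + 1)
        f[mid + 1:] = plateau_pn
        phase = np.array(["ramp"] * (mid + 1) + ["clamp"] * (n_samples - mid - 1),
                         dtype=object)
        truth = ForceTraceGroundTruth(peak_pn=peak_pn, peak_time_ns=t[mid],
                                      plateau_pn=plateau_pn)
    else:
        raise RampClampError(f"unknown trace shape {shape!r}")
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=n_samples)
    dummy = np.cumsum(np.full(n_samples, 0.05))
    steered = dummy - f / 3.474  # nominal spring extension bookkeeping
    return ForceTrace(t, f, dummy, steered, phase), truth
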