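"""Geometric hydrogen-bond detection and occupancy statistics.

A donor–hydrogen–acceptor triplet is counted as bonded in a frame when the
donor–acceptor distance is ≤ 3.5 Å and the D–H···A arrangement deviates
from linearity by ≤ 30° (the VMD convention: the cutoff is the deviation
from 180°, not the raw D–H–A angle).  When the structure carries no
hydrogens a documented distance-only fallback is available.

Occupancy (survival ratio) of a bond is the fraction of frames in which it
is present; residue-pair bookkeeping takes the per-frame union over all
atom-level triplets of the pair.  The module also provides the two
dissociation-probability estimators and force-response typing of bonds
into types I (insensitive), II (force-enhanced) and III (force-weakened).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import EmptyInputError, ModeError, PartitionError, RampClampError
from .structures import Structure, Trajectory

ResidueKey = Tuple[str, str, int]  # (chain_id, res_name, res_seq)
PairKey = Tuple[ResidueKey, ResidueKey]


@dataclass(frozen=True)
class HBondTriplet:
    """An atom-level donor–hydrogen–acceptor contact."""

    donor: int
    hydrogen: Optional[int]
    acceptor: int
    donor_res: ResidueKey
    acceptor_res: ResidueKey


@dataclass
class DissociationEstimate:
    probability: float
    upper_bound_95: float
    method: str
    n_frames: Optional[int] = None


@dataclass
class BondTypeCall:
    """Force-response classification of one residue pair."""

    pair: PairKey
    occ_static: float
    occ_force: float
    delta: float
    bond_type: str  # "I", "II" or "III"
    p_value: Optional[float] = None


# ------------------------------------------------- donor/acceptor chemistry

#: residue-level donor/acceptor chemistry: N and O atoms accept; N/O atoms
#: with a covalently attached hydrogen (< 1.2 Å) donate.
DONOR_ELEMENTS = {"N", "O"}
ACCEPTOR_ELEMENTS = {"N", "O"}
COVALENT_H_CUTOFF = 1.2


def find_donors(structure: Structure) -> List[Tuple[int, Optional[int]]]:
    """Return (donor_index, hydrogen_index) pairs from topology geometry.

    A heavy atom is a donor once per attached hydrogen.  Uses the
    structure's own coordinates as the topology frame.
    """
    X = structure.coords
    h_idx = [i for i, a in enumerate(structure.atoms) if a.element == "H"]
    heavy = [i for i, a in enumerate(structure.atoms)
             if a.element in DONOR_ELEMENTS]
    out = []
    for h in h_idx:
        if not heavy:
            break
        d = np.linalg.norm(X[heavy] - X[h], axis=1)
        j = int(np.argmin(d))
        if d[j] < COVALENT_H_CUTOFF:
            out.append((heavy[j], h))
    return out


def find_acceptors(structure: Structure) -> List[int]:
    return [i for i, a in enumerate(structure.atoms)
            if a.element in ACCEPTOR_ELEMENTS]


# ----------------------------------------------------------------- detection

def _linearity_deviation_deg(xd, xh, xa) -> np.ndarray:
    """Deviation of D–H···A from linear, in degrees (0 = perfectly linear)."""
    u = xd - xh
    v = xa - xh
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    cosang = np.sum(u * v, axis=-1) / (nu * nv)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return 180.0 - ang


def detect_frame(structure_or_coords, donors: Sequence[Tuple[int, Optional[int]]],
                 acceptors: Sequence[int], d_cut: float = 3.5,
                 ang_cut: float = 30.0, atom_table: Optional[Structure] = None,
                 distance_only: bool = False) -> set:
    """Detect H-bond triplets in one frame.

    Parameters
    ----------
    structure_or_coords : Structure or (n_atoms, 3) array
        When an array is given, ``atom_table`` must supply atom identities.
    donors : sequence of (donor_index, hydrogen_index)
        ``hydrogen_index`` may be None only in distance-only mode.
    distance_only : bool
        Skip the angle criterion (fallback for hydrogen-free structures).

    Returns
    -------
    set of HBondTriplet
    """
    if isinstance(structure_or_coords, Structure):
        table = structure_or_coords
        X = structure_or_coords.coords
    else:
        table = atom_table
        X = np.asarray(structure_or_coords, dtype=float)
        if table is None:
            raise RampClampError("atom_table required when passing raw coords")
    if not distance_only and any(h is None for _, h in donors):
        raise ModeError(
            "angle mode requested but a donor lacks a hydrogen; "
            "pass distance_only=True for hydrogen-free structures"
        )
    out = set()
    for (d, h), a in itertools.product(donors, acceptors):
        if a == d or a == h:
            continue
        if np.linalg.norm(X[d] - X[a]) > d_cut:
            continue
        if not distance_only:
            dev = float(_linearity_deviation_deg(X[d], X[h], X[a]))
            if dev > ang_cut:
                continue
        out.add(HBondTriplet(
            donor=d, hydrogen=h, acceptor=a,
            donor_res=table.atoms[d].residue_key,
            acceptor_res=table.atoms[a].residue_key,
        ))
    return out


def detect_trajectory(traj: Trajectory, donors, acceptors, d_cut: float = 3.5,
                      ang_cut: float = 30.0,
                      distance_only: bool = False) -> List[set]:
    """Vectorised per-frame detection over a trajectory.

    Equivalent to calling :func:`detect_frame` on every frame; distances
    and angles for all (donor, acceptor) pairs are evaluated in one
    broadcast per trajectory.
    """
    if not donors or not acceptors:
        return [set() for _ in range(traj.n_frames)]
    if not distance_only and any(h is None for _, h in donors):
        raise ModeError("angle mode requires hydrogens for every donor")
    d_idx = np.array([d for d, _ in donors])
    a_idx = np.array(list(acceptors))
    X = traj.coords  # (F, N, 3)
    XD = X[:, d_idx, :][:, :, None, :]   # (F, nD, 1, 3)
    XA = X[:, a_idx, :][:, None, :, :]   # (F, 1, nA, 3)
    dist = np.linalg.norm(XD - XA, axis=-1)           # (F, nD, nA)
    ok = dist <= d_cut
    if not distance_only:
        h_idx = np.array([h for _, h in donors])
        XH = X[:, h_idx, :][:, :, None, :]
        dev = _linearity_deviation_deg(XD, XH, XA)
        ok &= dev <= ang_cut
    # mask self-pairs
    same = d_idx[:, None] == a_idx[None, :]
    ok &= ~same[None, :, :]
    table = traj.structure
    trips = {}
    frames_out = []
    for f in range(traj.n_frames):
        s = set()
        for i, j in zip(*np.nonzero(ok[f])):
            key = (int(i), int(j))
            trip = trips.get(key)
            if trip is None:
                d = int(d_idx[i])
                a = int(a_idx[j])
                trip = HBondTriplet(
                    donor=d,
                    hydrogen=None if distance_only else int(donors[i][1]),
                    acceptor=a,
                    donor_res=table.atoms[d].residue_key,
                    acceptor_res=table.atoms[a].residue_key,
                )
                trips[key] = trip
            s.add(trip)
        frames_out.append(s)
    return frames_out


def interfacial_filter(bonds, chain_set_A, chain_set_B):
    """Keep only bonds whose donor and acceptor sit on opposite chain sets."""
    A, B = set(chain_set_A), set(chain_set_B)
    if A & B:
        raise PartitionError("chain sets must be disjoint")

    def _is_cross(t: HBondTriplet) -> bool:
        cd, ca = t.donor_res[0], t.acceptor_res[0]
        return (cd in A and ca in B) or (cd in B and ca in A)

    if isinstance(bonds, set):
        return {t for t in bonds if _is_cross(t)}
    return [interfacial_filter(fr, A, B) for fr in bonds]


def nhb_series(frames_bonds: Sequence[set]) -> np.ndarray:
    """Per-frame interfacial H-bond count N_HB."""
    return np.array([len(fr) for fr in frames_bonds], dtype=int)


# ----------------------------------------------------------------- occupancy

def pair_key_of(triplet: HBondTriplet, chain_set_A=None) -> PairKey:
    """Residue-pair key, ordered so the chain-set-A residue comes first
    (falling back to lexicographic order when no chain set is given)."""
    dres, ares = triplet.donor_res, triplet.acceptor_res
    if chain_set_A is not None:
        if dres[0] in set(chain_set_A):
            return (dres, ares)
        return (ares, dres)
    return (dres, ares) if (dres[0], dres[2]) <= (ares[0], ares[2]) else (ares, dres)


def presence_matrix(frames_bonds: Sequence[set], chain_set_A=None
                    ) -> Dict[PairKey, np.ndarray]:
    """Per-frame presence of each residue pair (union over atom triplets)."""
    n = len(frames_bonds)
    out: Dict[PairKey, np.ndarray] = {}
    for f, fr in enumerate(frames_bonds):
        for t in fr:
            key = pair_key_of(t, chain_set_A)
            if key not in out:
                out[key] = np.zeros(n, dtype=bool)
            out[key][f] = True
    return out


def occupancy(frames_bonds: Sequence[set], pair_key: PairKey,
              chain_set_A=None) -> float:
    """Survival ratio of one residue pair: fraction of frames present."""
    if len(frames_bonds) == 0:
        raise EmptyInputError("occupancy needs at least one frame")
    pm = presence_matrix(frames_bonds, chain_set_A)
    if pair_key not in pm:
        return 0.0
    return float(pm[pair_key].mean())


def occupancies(frames_bonds: Sequence[set], chain_set_A=None
                ) -> Dict[PairKey, float]:
    if len(frames_bonds) == 0:
        raise EmptyInputError("occupancy needs at least one frame")
    return {k: float(v.mean())
            for k, v in presence_matrix(frames_bonds, chain_set_A).items()}


def occupancy_table(per_run_occupancies: Sequence[Dict[PairKey, float]],
                    expected_pairs: Optional[Sequence[PairKey]] = None):
    """Aggregate per-run occupancies to a Table-1-style DataFrame.

    Columns: residue_A, residue_B, plus run_<i>, occupancy_mean,
    occupancy_sd (sample SD, n−1), n_runs.  Pairs absent from a run count
    as occupancy 0 in that run; ``expected_pairs`` forces rows (with zero
    occupancy) for monitored pairs that never formed.
    """
    import pandas as pd

    all_keys = {k for run in per_run_occupancies for k in run}
    if expected_pairs is not None:
        all_keys |= set(expected_pairs)
    keys = sorted(all_keys,
                  key=lambda k: (k[0][0], k[0][2], k[1][0], k[1][2]))
    rows = []
    n_runs = len(per_run_occupancies)
    for k in keys:
        vals = np.array([run.get(k, 0.0) for run in per_run_occupancies])
        row = {
            "residue_A": f"{k[0][1]}{k[0][2]}",
            "residue_B": f"{k[1][1]}{k[1][2]}",
            "chain_A": k[0][0],
            "chain_B": k[1][0],
        }
        for i, v in enumerate(vals, start=1):
            row[f"run_{i}"] = v
        row["occupancy_mean"] = vals.mean()
        row["occupancy_sd"] = vals.std(ddof=1) if n_runs > 1 else 0.0
        row["n_runs"] = n_runs
        rows.append(row)
    return pd.DataFrame(rows)


# ------------------------------------------------- dissociation probability

def dissociation_probability(occupancy_values=None, nhb_per_frame=None,
                             method: str = "independence_product"
                             ) -> DissociationEstimate:
    """Estimate the probability that every interfacial bond is broken.

    ``independence_product`` multiplies per-bond breakage probabilities
    Π_i (1 − occ_i); ``empirical_all_broken`` is the observed fraction of
    frames with zero interfacial bonds, with a rule-of-three 95% upper
    bound (3/n) when no such frame was observed.
    """
    if method == "independence_product":
        if occupancy_values is None or len(occupancy_values) == 0:
            raise EmptyInputError("independence_product needs occupancies")
        occ = np.asarray(list(occupancy_values), dtype=float)
        if np.any((occ < 0) | (occ > 1)):
            raise RampClampError("occupancies must lie in [0, 1]")
        p = float(np.prod(1.0 - occ))
        return DissociationEstimate(p, p, method)
    if method == "empirical_all_broken":
        if nhb_per_frame is None or len(nhb_per_frame) == 0:
            raise EmptyInputError("empirical_all_broken needs an N_HB series")
        nhb = np.asarray(nhb_per_frame)
        n = len(nhb)
        k = int(np.sum(nhb == 0))
        p = k / n
        upper = p if k > 0 else 3.0 / n
        return DissociationEstimate(p, upper, method, n_frames=n)
    raise RampClampError(f"unknown dissociation method {method!r}")


# --------------------------------------------------------- force typing

def classify_force_response(occ_static_runs: Dict[PairKey, Sequence[float]],
                            occ_force_runs: Dict[PairKey, Sequence[float]],
                            delta_min: float = 0.05,
                            test: Optional[str] = "welch",
                            alpha: float = 0.05) -> List[BondTypeCall]:
    """Type each residue pair by its occupancy response to tensile force.

    delta = mean(force) − mean(static).  Type II ⇔ delta ≥ +delta_min,
    type III ⇔ delta ≤ −delta_min, type I otherwise.  With ``test="welch"``
    a two-sample Welch t-test gates the call: non-significant changes are
    demoted to type I (degenerate zero-variance cases fall back to the
    delta rule).  Swapping the two conditions maps II↔III and fixes I.
    """
    if set(occ_static_runs) != set(occ_force_runs):
        raise KeyError("static and force conditions list different pairs")
    calls = []
    for pair in sorted(occ_static_runs,
                       key=lambda k: (k[0][0], k[0][2], k[1][0], k[1][2])):
        s = np.asarray(list(occ_static_runs[pair]), dtype=float)
        f = np.asarray(list(occ_force_runs[pair]), dtype=float)
        ms, mf = float(s.mean()), float(f.mean())
        delta = mf - ms
        p_value = None
        significant = True
        if test == "welch":
            if len(s) < 2 or len(f) < 2:
                raise RampClampError("welch gate needs ≥2 replicates per condition")
            with np.errstate(all="ignore"):
                p_value = float(stats.ttest_ind(f, s, equal_var=False).pvalue)
            if np.isnan(p_value):
                p_value = None  # zero variance both sides: delta rule decides
            else:
                significant = p_value < alpha
        elif test is not None:
            raise RampClampError(f"unknown test {test!r}")
        if delta >= delta_min and significant:
            btype = "II"
        elif delta <= -delta_min and significant:
            btype = "III"
        else:
            btype = "I"
        calls.append(BondTypeCall(pair, ms, mf, delta, btype, p_value))
    return calls
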