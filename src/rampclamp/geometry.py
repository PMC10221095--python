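"""Superposition and trajectory geometry metrics.

Implements Kabsch least-squares superposition, per-frame Cα-RMSD,
per-residue RMSF, radius of gyration, and the three binding-pocket
descriptors used for the CD47/CD172a system: the centroid distance *H*
between two loops, the angle *α* between a β-strand axis and a two-atom
vector, and the inter-strand angle *θ*.  Strand axes are the first
principal component of the ordered Cα coordinates, oriented N→C.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateGeometryError, InsufficientFramesError, SelectionError
from .structures import Trajectory


@dataclass
class StrandAxis:
    """A fitted β-strand axis: a point on the axis and a unit N→C direction."""

    origin: np.ndarray
    direction: np.ndarray


def kabsch_superpose(mobile_coords, ref_coords, weights=None):
    """Optimal rigid superposition of ``mobile`` onto ``ref`` (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimises the (weighted) RMSD to
    ``ref``.  The rotation is always proper (det = +1).

    Raises
    ------
    DegenerateGeometryError
        Fewer than 3 points, or all points collinear.
    """
    P = np.asarray(mobile_coords, dtype=float)
    Q = np.asarray(ref_coords, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise DegenerateGeometryError("coordinate sets must both be (n, 3)")
    n = P.shape[0]
    if n < 3:
        raise DegenerateGeometryError("superposition needs at least 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    p_cm = w @ P
    q_cm = w @ Q
    P0 = P - p_cm
    Q0 = Q - q_cm
    # collinearity check on the reference set
    _, sv, _ = np.linalg.svd(Q0 * np.sqrt(w)[:, None])
    if sv[1] < 1e-10 * max(sv[0], 1.0):
        raise DegenerateGeometryError("points are collinear; rotation underdetermined")
    H = (P0 * w[:, None]).T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = q_cm - R @ p_cm
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.sum(w * np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def rmsd_series(traj: Trajectory, selection, ref_frame: int = 0,
                weights=None) -> np.ndarray:
    """Per-frame RMSD (Å) to a reference frame after optimal superposition."""
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise SelectionError("empty selection for RMSD")
    ref = traj.coords[ref_frame][sel]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, _, out[f] = kabsch_superpose(traj.coords[f][sel], ref, weights)
    out[ref_frame] = 0.0  # exact by definition; avoids sqrt-rounding dust
    return out


def superpose_trajectory(traj_coords: np.ndarray, sel: np.ndarray,
                         ref: np.ndarray) -> np.ndarray:
    """Superpose every frame onto ``ref`` using the selected atoms."""
    out = np.empty_like(traj_coords)
    for f in range(traj_coords.shape[0]):
        R, t, _ = kabsch_superpose(traj_coords[f][sel], ref, None)
        out[f] = traj_coords[f] @ R.T + t
    return out


def rmsf_per_residue(traj: Trajectory, selection, superpose: bool = True,
                     n_iter: int = 2) -> np.ndarray:
    """Per-atom RMSF (Å) over a trajectory, for the selected (Cα) atoms.

    Frames are first superposed onto their running mean structure
    (``n_iter`` refinement passes); RMSF_i = sqrt(<|r_i - <r_i>|^2>).
    Set ``superpose=False`` to compute fluctuations in the lab frame.
    """
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise SelectionError("empty selection for RMSF")
    if traj.n_frames < 2:
        raise InsufficientFramesError("RMSF needs at least 2 frames")
    X = traj.coords[:, sel, :].copy()
    if superpose:
        ref = X[0]
        for _ in range(n_iter):
            X = superpose_trajectory(X, np.arange(sel.size), ref)
            ref = X.mean(axis=0)
    mean = X.mean(axis=0)
    return np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=0))


def radius_of_gyration(coords, masses=None) -> float:
    """Mass-weighted radius of gyration (Å)."""
    X = np.atleast_2d(np.asarray(coords, dtype=float))
    if masses is None:
        m = np.ones(X.shape[0])
    else:
        m = np.asarray(masses, dtype=float)
        if np.any(m <= 0):
            raise DegenerateGeometryError("masses must be positive")
    cm = (m @ X) / m.sum()
    return float(np.sqrt(np.sum(m * np.sum((X - cm) ** 2, axis=1)) / m.sum()))


def rgyr_series(traj: Trajectory, selection=None) -> np.ndarray:
    """Per-frame radius of gyration of the selected atoms (default: all)."""
    if selection is None:
        sel = np.arange(traj.n_atoms)
    else:
        sel = np.asarray(selection, dtype=int)
    m = traj.structure.masses[sel]
    return np.array([radius_of_gyration(traj.coords[f][sel], m)
                     for f in range(traj.n_frames)])


def centroid(coords, weights=None) -> np.ndarray:
    """(Weighted) mean position of a point set."""
    X = np.atleast_2d(np.asarray(coords, dtype=float))
    if weights is None:
        return X.mean(axis=0)
    w = np.asarray(weights, dtype=float)
    return (w @ X) / w.sum()


def strand_axis(ca_coords_ordered) -> StrandAxis:
    """Fit a β-strand axis through ordered Cα positions.

    The direction is the principal eigenvector of the coordinate
    covariance, sign-fixed so that ``direction · (last − first) > 0``
    (N→C orientation).  Reversing the residue order flips the axis.
    """
    X = np.asarray(ca_coords_ordered, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise DegenerateGeometryError("strand axis needs ≥3 ordered Cα positions")
    c = X.mean(axis=0)
    X0 = X - c
    cov = X0.T @ X0
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] < 1e-12:
        raise DegenerateGeometryError("all strand points coincide")
    d = evecs[:, -1]
    span = X[-1] - X[0]
    if d @ span < 0:
        d = -d
    d = d / np.linalg.norm(d)
    return StrandAxis(origin=c, direction=d)


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    cosang = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def metric_H(traj: Trajectory, cd_loop_sel, de_loop_sel) -> np.ndarray:
    """Per-frame distance (Å) between the centroids of two loop selections."""
    a = np.asarray(cd_loop_sel, dtype=int)
    b = np.asarray(de_loop_sel, dtype=int)
    if a.size == 0 or b.size == 0:
        raise SelectionError("loop selections must be non-empty")
    ca = traj.coords[:, a, :].mean(axis=1)
    cb = traj.coords[:, b, :].mean(axis=1)
    return np.linalg.norm(ca - cb, axis=1)


def metric_alpha(traj: Trajectory, c_strand_sel, atom_a: int,
                 atom_b: int) -> np.ndarray:
    """Per-frame angle (deg) between a strand axis and the a→b atom vector."""
    sel = np.asarray(c_strand_sel, dtype=int)
    if atom_a == atom_b:
        raise DegenerateGeometryError("metric_alpha needs two distinct atoms")
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        axis = strand_axis(traj.coords[f][sel])
        v = traj.coords[f][atom_b] - traj.coords[f][atom_a]
        if np.linalg.norm(v) < 1e-12:
            raise DegenerateGeometryError("reference atoms coincide")
        out[f] = _angle_deg(axis.direction, v)
    return out


def metric_theta(traj: Trajectory, g_strand_sel, c_strand_sel) -> np.ndarray:
    """Per-frame angle (deg) between two oriented β-strand axes."""
    sa = np.asarray(g_strand_sel, dtype=int)
    sb = np.asarray(c_strand_sel, dtype=int)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        ax_a = strand_axis(traj.coords[f][sa])
        ax_b = strand_axis(traj.coords[f][sb])
        out[f] = _angle_deg(ax_a.direction, ax_b.direction)
    return out
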