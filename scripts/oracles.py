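"""Independent oracles and tiny fixtures used by the acceptance script.

These deliberately re-implement the checked quantities with direct loops
or exhaustive search, so they share no code with the package paths they
validate.
"""

import numpy as np

from rampclamp import smd
from rampclamp.structures import Atom, Structure


def random_frame(seed, n_donors=5, n_acceptors=8):
    """A random frame with explicit hydrogens bonded to each donor."""
    rng = np.random.default_rng(seed)
    atoms, donors = [], []
    serial = 1
    for i in range(n_donors):
        xn = rng.uniform(0, 12, 3)
        xh = xn + rng.normal(scale=0.4, size=3)
        xh = xn + (xh - xn) / np.linalg.norm(xh - xn)
        atoms.append(Atom(serial, f"N{i}", "N", "XXX", i + 1, "A", xn))
        nd = len(atoms) - 1
        serial += 1
        atoms.append(Atom(serial, f"H{i}", "H", "XXX", i + 1, "A", xh))
        donors.append((nd, len(atoms) - 1))
        serial += 1
    acceptors = []
    for i in range(n_acceptors):
        atoms.append(Atom(serial, f"O{i}", "O", "YYY", 100 + i, "B",
                          rng.uniform(0, 12, 3)))
        acceptors.append(len(atoms) - 1)
        serial += 1
    return Structure(atoms), donors, acceptors


def brute_detect(X, donors, acceptors, d_cut=3.5, ang_cut=30.0):
    """Exhaustive O(N²) H-bond enumeration with independent criterion math."""
    found = set()
    for (d, h) in donors:
        for a in acceptors:
            if a in (d, h):
                continue
            if np.sqrt(np.sum((X[d] - X[a]) ** 2)) > d_cut:
                continue
            u = X[d] - X[h]
            v = X[a] - X[h]
            ang = np.degrees(np.arccos(np.clip(
                u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)))
            if 180.0 - ang <= ang_cut:
                found.add((d, a))
    return found


def grid_min_rmsd(P, Q, levels=4, n0=14):
    """Minimum RMSD by nested grid search over rotations (Euler angles)."""
    from scipy.spatial.transform import Rotation

    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)

    def rmsd_for(angles):
        R = Rotation.from_euler("zyz", angles).as_matrix()
        return np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1)))

    best = (np.inf, np.zeros(3))
    span = np.pi
    centers = np.zeros(3)
    for _ in range(levels):
        grid = np.linspace(-span, span, n0)
        for a in centers[0] + grid:
            for b in centers[1] + grid:
                for c in centers[2] + grid:
                    r = rmsd_for([a, b, c])
                    if r < best[0]:
                        best = (r, np.array([a, b, c]))
        centers = best[1]
        span = 2 * span / (n0 - 1)
    return best[0]


def tether_model(rest_length=0.0, k=1.0, anchor=(0, 0, 0), bead=(0, 0, 3.0)):
    """Fixed anchor plus one mobile bead on a single spring."""
    s = Structure([
        Atom(1, "CA", "C", "GLY", 1, "A", anchor),
        Atom(2, "CA", "C", "GLY", 2, "B", bead),
    ])
    return smd.ENMModel(
        coords=s.coords, masses=s.masses,
        springs=np.array([[0, 1]]), rest_lengths=np.array([rest_length]),
        stiffness=np.array([k]), breakable=np.array([False]), atoms=s,
    )
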