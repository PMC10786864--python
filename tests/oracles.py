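"""Independent reference implementations used only to check the package.

Each oracle deliberately takes a different algorithmic route from the
code under test: an explicit Gotoh dynamic program for global alignment,
the quaternion characteristic-polynomial closed form for superposition
RMSD, all-pairs loops for contact detection, and exhaustive enumeration
for conformer-pair counting.
"""

from __future__ import annotations

import numpy as np

NEG_INF = float("-inf")


def gotoh_global(seq_a: str, seq_b: str, match: float = 1.0,
                 mismatch: float = 0.0, gap_open: float = -10.0,
                 gap_extend: float = -0.5):
    """Affine-gap global alignment DP with traceback.

    Returns (score, identity) where identity = identical aligned
    positions / alignment length (gap columns included).
    """
    n, m = len(seq_a), len(seq_b)
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)  # gap in seq_b (consume a)
    Y = np.full((n + 1, m + 1), NEG_INF)  # gap in seq_a (consume b)
    ptr_m = np.zeros((n + 1, m + 1), dtype="U1")  # predecessor state of M
    ptr_x = np.zeros((n + 1, m + 1), dtype="U1")
    ptr_y = np.zeros((n + 1, m + 1), dtype="U1")
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * (i - 1)
        ptr_x[i, 0] = "M" if i == 1 else "X"
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * (j - 1)
        ptr_y[0, j] = "M" if j == 1 else "Y"
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if seq_a[i - 1] == seq_b[j - 1] else mismatch
            options = (("M", M[i - 1, j - 1]), ("X", X[i - 1, j - 1]),
                       ("Y", Y[i - 1, j - 1]))
            ptr_m[i, j], best = max(options, key=lambda kv: kv[1])
            M[i, j] = best + s
            if M[i - 1, j] + gap_open >= X[i - 1, j] + gap_extend:
                X[i, j], ptr_x[i, j] = M[i - 1, j] + gap_open, "M"
            else:
                X[i, j], ptr_x[i, j] = X[i - 1, j] + gap_extend, "X"
            if M[i, j - 1] + gap_open >= Y[i, j - 1] + gap_extend:
                Y[i, j], ptr_y[i, j] = M[i, j - 1] + gap_open, "M"
            else:
                Y[i, j], ptr_y[i, j] = Y[i, j - 1] + gap_extend, "Y"
    tables = {"M": (M, ptr_m), "X": (X, ptr_x), "Y": (Y, ptr_y)}
    state = max(tables, key=lambda k: tables[k][0][n, m])
    score = tables[state][0][n, m]
    i, j = n, m
    identical = 0
    length = 0
    while i > 0 or j > 0:
        length += 1
        prev = tables[state][1][i, j]
        if state == "M":
            if seq_a[i - 1] == seq_b[j - 1]:
                identical += 1
            i, j = i - 1, j - 1
        elif state == "X":
            i -= 1
        else:
            j -= 1
        state = prev
    return float(score), identical / length


def qcp_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimum superposition RMSD via the quaternion characteristic
    polynomial key matrix (largest eigenvalue), no SVD involved."""
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    n = len(a)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    ga = float(np.sum(ac * ac))
    gb = float(np.sum(bc * bc))
    r = ac.T @ bc
    key = np.array([
        [r[0, 0] + r[1, 1] + r[2, 2], r[1, 2] - r[2, 1],
         r[2, 0] - r[0, 2], r[0, 1] - r[1, 0]],
        [r[1, 2] - r[2, 1], r[0, 0] - r[1, 1] - r[2, 2],
         r[0, 1] + r[1, 0], r[0, 2] + r[2, 0]],
        [r[2, 0] - r[0, 2], r[0, 1] + r[1, 0],
         -r[0, 0] + r[1, 1] - r[2, 2], r[1, 2] + r[2, 1]],
        [r[0, 1] - r[1, 0], r[0, 2] + r[2, 0],
         r[1, 2] + r[2, 1], -r[0, 0] - r[1, 1] + r[2, 2]],
    ])
    lam = float(np.linalg.eigvalsh(key)[-1])
    return float(np.sqrt(max(0.0, ga + gb - 2.0 * lam) / n))


def allpairs_contacts(chain_a, chain_b, vdw, tol: float = 0.5):
    """Vectorized all-pairs residue contact oracle.

    Returns {(key_a, key_b): min_dist} over contacting residue pairs.
    """
    def arrays(chain):
        coords, radii, keys = [], [], []
        for res in chain.residues:
            for atom in res.atoms:
                coords.append(atom.coord)
                radii.append(vdw.radius(atom.element))
                keys.append(res.key)
        return np.asarray(coords), np.asarray(radii), keys

    ca, ra, ka = arrays(chain_a)
    cb, rb, kb = arrays(chain_b)
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
    hit = d < (ra[:, None] + rb[None, :] + tol)
    out: dict[tuple, float] = {}
    for ia, ib in zip(*np.nonzero(hit)):
        pair = (ka[ia], kb[ib])
        dist = float(d[ia, ib])
        if dist < out.get(pair, np.inf):
            out[pair] = dist
    return out


def count_conformer_pairs(edges, conformers) -> int:
    """Exhaustive enumeration of conformer-resolved interactions."""
    total = 0
    for u, v in edges:
        cu = [f"{u}#{i}" for i in range(conformers[u])]
        cv = [f"{v}#{i}" for i in range(conformers[v])]
        seen = set()
        for a in cu:
            for b in cv:
                seen.add(frozenset((a, b)) if a != b else frozenset((a,)))
        total += len(seen)
    return total


def bootstrap_ci_width(values: np.ndarray, n_boot: int = 10_000,
                       seed: int = 0) -> float:
    """Percentile-bootstrap 95% CI width of the mean."""
    rng = np.random.default_rng(seed)
    values = np.asarray(values, float)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(hi - lo)
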