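"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own code paths: dense covariance
eigendecomposition instead of SVD, explicit rotation grids instead of the
closed-form fit, naive loops instead of vectorised formulas.
"""

import itertools
import math

import numpy as np

_GRID_CACHE: dict[float, np.ndarray] = {}


def euler_grid_rotations(step_deg: float) -> np.ndarray:
    """All ZYZ Euler rotations on a regular grid, as a (K, 3, 3) array."""
    if step_deg in _GRID_CACHE:
        return _GRID_CACHE[step_deg]
    step = math.radians(step_deg)
    alphas = np.arange(0.0, 2 * math.pi, step)
    betas = np.arange(0.0, math.pi + 1e-12, step)
    gammas = np.arange(0.0, 2 * math.pi, step)

    def rz(t):
        c, s = np.cos(t), np.sin(t)
        out = np.zeros((t.size, 3, 3))
        out[:, 0, 0] = c
        out[:, 0, 1] = -s
        out[:, 1, 0] = s
        out[:, 1, 1] = c
        out[:, 2, 2] = 1.0
        return out

    def ry(t):
        c, s = np.cos(t), np.sin(t)
        out = np.zeros((t.size, 3, 3))
        out[:, 0, 0] = c
        out[:, 0, 2] = s
        out[:, 2, 0] = -s
        out[:, 2, 2] = c
        out[:, 1, 1] = 1.0
        return out

    ra = rz(alphas)  # (A,3,3)
    rb = ry(betas)
    rg = rz(gammas)
    ab = np.einsum("aij,bjk->abik", ra, rb).reshape(-1, 3, 3)
    abg = np.einsum("mij,gjk->mgik", ab, rg).reshape(-1, 3, 3)
    _GRID_CACHE[step_deg] = abg
    return abg


def grid_min_rmsd(mobile: np.ndarray, target: np.ndarray, step_deg: float) -> float:
    """Best RMSD achievable by any grid rotation (after centring both sets)."""
    p = mobile - mobile.mean(axis=0)
    q = target - target.mean(axis=0)
    n = p.shape[0]
    rotations = euler_grid_rotations(step_deg)
    best = np.inf
    chunk = 200_000
    for lo in range(0, rotations.shape[0], chunk):
        rot = rotations[lo : lo + chunk]
        moved = np.einsum("kij,nj->kni", rot, p)
        sq = np.sum((moved - q) ** 2, axis=(1, 2)) / n
        best = min(best, float(sq.min()))
    return math.sqrt(best)


def dense_covariance_modes(data: np.ndarray, k: int):
    """Eigendecomposition of the explicitly formed covariance matrix.

    ``data`` must already be column-centred.  Returns (eigenvalues,
    eigenvectors) for the top-k modes, eigenvalues non-increasing,
    eigenvectors as rows.
    """
    m = data.shape[0]
    cov = (data.T @ data) / (m - 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    return w[order][:k], v[:, order][:, :k].T


def naive_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    total = 0.0
    for pa, pb in zip(a, b):
        total += sum((x - y) ** 2 for x, y in zip(pa, pb))
    return math.sqrt(total / len(a))


def naive_rmsf(coords: np.ndarray) -> np.ndarray:
    m, n, _ = coords.shape
    mean = coords.mean(axis=0)
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for mi in range(m):
            d = coords[mi, i] - mean[i]
            acc += d @ d
        out[i] = math.sqrt(acc / m)
    return out


def sasa_sampling_oracle(
    coords: np.ndarray, radii: np.ndarray, probe: float, n_points: int = 10_000, seed: int = 0
) -> np.ndarray:
    """High-density random-direction SASA estimate, independent per atom."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n_points, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    expanded = radii + probe
    n = coords.shape[0]
    areas = np.zeros(n)
    for i in range(n):
        surface = coords[i] + expanded[i] * pts
        exposed = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            exposed &= np.sum((surface - coords[j]) ** 2, axis=1) >= expanded[j] ** 2
        areas[i] = 4 * math.pi * expanded[i] ** 2 * exposed.mean()
    return areas


def enumerate_bipartite_nls(seq, min_spacer=9, max_spacer=12, cutoff=4.0):
    """Window-by-window enumeration of the bipartite NLS definition."""
    basic = set("KR")
    hits = []
    for i in range(len(seq) - 1):
        if seq[i] in basic and seq[i + 1] in basic:
            for spacer in range(min_spacer, max_spacer + 1):
                w = i + 2 + spacer
                window = seq[w : w + 5]
                if len(window) < 5:
                    continue
                nb = sum(c in basic for c in window)
                if nb < 3:
                    continue
                score = 2 + nb + 0.5 * sum(c in basic for c in seq[i + 2 : w])
                if score >= cutoff:
                    last = max(j for j, c in enumerate(window) if c in basic)
                    hits.append((i + 1, w + last + 1, score))
    return hits


def exhaustive_permutation_p(values, n_open, observed_delta):
    """All C(M, n_open) open-label assignments; one-sided p for delta."""
    m = len(values)
    n_closed = m - n_open
    count = 0
    total = 0
    for idx in itertools.combinations(range(m), n_open):
        mask = np.zeros(m, dtype=bool)
        mask[list(idx)] = True
        d = values[mask].mean() - values[~mask].mean()
        total += 1
        if d >= observed_delta - 1e-12:
            count += 1
    return count / total
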