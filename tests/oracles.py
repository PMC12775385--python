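"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the library's code paths: flood fill instead of
``scipy.ndimage.label``, explicit cubical-complex counting for the Euler
characteristic, and exhaustive threshold search with literal two-level
image reconstruction for the moment-preserving binarization.
"""

from __future__ import annotations

import numpy as np


def floodfill_components(mask: np.ndarray, connectivity: int) -> int:
    """Number of connected true-regions by explicit stack-based flood fill."""
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                (0, 1), (1, -1), (1, 0), (1, 1)]
    elif connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        raise ValueError(connectivity)
    seen = np.zeros_like(mask, dtype=bool)
    ny, nx = mask.shape
    count = 0
    for i0 in range(ny):
        for j0 in range(nx):
            if mask[i0, j0] and not seen[i0, j0]:
                count += 1
                stack = [(i0, j0)]
                seen[i0, j0] = True
                while stack:
                    i, j = stack.pop()
                    for di, dj in nbrs:
                        a, b = i + di, j + dj
                        if 0 <= a < ny and 0 <= b < nx \
                                and mask[a, b] and not seen[a, b]:
                            seen[a, b] = True
                            stack.append((a, b))
    return count


def floodfill_holes(mask: np.ndarray) -> int:
    """Background 4-components not reachable from the border (flood fill)."""
    mask = np.asarray(mask, dtype=bool)
    bg = ~mask
    ny, nx = mask.shape
    seen = np.zeros_like(bg)
    stack = [(i, j) for i in range(ny) for j in (0, nx - 1) if bg[i, j]]
    stack += [(i, j) for j in range(nx) for i in (0, ny - 1) if bg[i, j]]
    for i, j in stack:
        seen[i, j] = True
    while stack:
        i, j = stack.pop()
        for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            a, b = i + di, j + dj
            if 0 <= a < ny and 0 <= b < nx and bg[a, b] and not seen[a, b]:
                seen[a, b] = True
                stack.append((a, b))
    interior = bg & ~seen
    return floodfill_components(interior, 4)


def euler_characteristic(mask: np.ndarray) -> int:
    """V - E + F of the union of closed unit squares over true pixels.

    For the closed-pixel complex this equals (8-connected foreground
    components) minus (4-connected holes).
    """
    mask = np.asarray(mask, dtype=bool)
    verts: set[tuple[int, int]] = set()
    edges: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    faces = 0
    for i, j in zip(*np.nonzero(mask)):
        faces += 1
        c = [(i, j), (i, j + 1), (i + 1, j), (i + 1, j + 1)]
        verts.update(c)
        edges.update({(c[0], c[1]), (c[2], c[3]), (c[0], c[2]), (c[1], c[3])})
    return len(verts) - len(edges) + faces


def moments_mismatch_by_threshold(hist: np.ndarray) -> np.ndarray:
    """Third-moment error of the literal two-level reconstruction, per t.

    For each threshold ``t`` the pixels with level <= t are replaced by
    one representative value and the rest by another, the pair chosen to
    reproduce the histogram mean and variance exactly; the entry is the
    absolute error of the reconstruction's third moment (inf where a
    class is empty).
    """
    hist = np.asarray(hist, dtype=float)
    p = hist / hist.sum()
    g = np.arange(256.0)
    m1 = float((p * g).sum())
    m2 = float((p * g**2).sum())
    m3 = float((p * g**3).sum())
    var = m2 - m1 * m1
    out = np.full(256, np.inf)
    q = np.cumsum(p)
    for t in range(256):
        qt = q[t]
        if qt <= 1e-12 or qt >= 1 - 1e-12:
            continue
        # two-point distribution with mass qt at za, 1-qt at zb matching
        # mean and variance
        za = m1 - np.sqrt(var * (1 - qt) / qt)
        zb = m1 + np.sqrt(var * qt / (1 - qt))
        recon_m3 = qt * za**3 + (1 - qt) * zb**3
        out[t] = abs(recon_m3 - m3)
    return out


def random_histogram(rng: np.random.Generator) -> np.ndarray:
    """Random 256-bin histogram from one of several families."""
    kind = rng.integers(4)
    if kind == 0:
        counts = rng.integers(0, 50, 256)
    elif kind == 1:  # bimodal
        n1, n2 = rng.integers(100, 5000, 2)
        a = np.clip(rng.normal(rng.integers(20, 110), rng.integers(3, 20), n1),
                    0, 255).astype(int)
        b = np.clip(rng.normal(rng.integers(120, 230), rng.integers(3, 20), n2),
                    0, 255).astype(int)
        counts = np.bincount(np.concatenate([a, b]), minlength=256)
    elif kind == 2:  # dominant peak with a dark tail, CT-like
        a = np.clip(rng.normal(108, 4, 10000), 0, 255).astype(int)
        b = np.clip(rng.normal(70, 6, rng.integers(10, 800)), 0, 255).astype(int)
        counts = np.bincount(np.concatenate([a, b]), minlength=256)
    else:
        counts = (rng.random(256) ** 4 * 100).astype(int)
    if counts.sum() == 0:
        counts[rng.integers(256)] = 1
    return counts.astype(np.int64)
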