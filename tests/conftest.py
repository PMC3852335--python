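"""Shared fixtures: small synthetic scenes and independent oracles."""
from __future__ import annotations

import numpy as np
import pytest

from cryptgrade import Grade, GradeParams, generate_biopsy_image
from cryptgrade.grades import DEFAULT_GRADE_PARAMS
from cryptgrade.synthetic import LabeledImage


@pytest.fixture(scope="session")
def normal_scene():
    """One seeded Normal-grade field with its ground truth."""
    return generate_biopsy_image(DEFAULT_GRADE_PARAMS[Grade.NORMAL], rng_seed=42)


@pytest.fixture(scope="session")
def grade3_scene():
    return generate_biopsy_image(DEFAULT_GRADE_PARAMS[Grade.III], rng_seed=42)


@pytest.fixture
def blank_image():
    return LabeledImage(np.full((120, 160), 128.0))


def make_disk_image(h=200, w=260, cx=130.0, cy=100.0, radius=40.0,
                    fg=70.0, bg=185.0):
    """Antialiased dark disk on a light background."""
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(xx - cx, yy - cy)
    img = np.where(r <= radius, fg, bg).astype(float)
    # one-pixel linear edge ramp so the gradient ridge is well defined
    edge = (r > radius) & (r < radius + 1)
    img[edge] = fg + (bg - fg) * (r[edge] - radius)
    return LabeledImage(img)


# ---------------------------------------------------------------------------
# Independent oracles (never the implementation under test)

def naive_dft(samples):
    """Literal O(K^2) double-loop DFT with the 1/K factor."""
    K = len(samples)
    out = np.zeros(K, dtype=complex)
    for u in range(K):
        acc = 0.0 + 0.0j
        for k in range(K):
            acc += samples[k] * np.exp(-2j * np.pi * u * k / K)
        out[u] = acc / K
    return out


def exhaustive_mst_weight(points):
    """Minimum spanning-tree weight by enumerating all labeled trees
    (Pruefer sequences); exponential, for n <= 7 only."""
    import itertools

    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n == 1:
        return 0.0
    if n == 2:
        return float(np.linalg.norm(pts[0] - pts[1]))
    dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    best = np.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        # decode the Pruefer sequence into tree edges
        degree = [1] * n
        for x in seq:
            degree[x] += 1
        seq_list = list(seq)
        total = 0.0
        deg = degree[:]
        import heapq
        leaves = [i for i in range(n) if deg[i] == 1]
        heapq.heapify(leaves)
        for x in seq_list:
            leaf = heapq.heappop(leaves)
            total += dist[leaf, x]
            deg[x] -= 1
            if deg[x] == 1:
                heapq.heappush(leaves, x)
        u = heapq.heappop(leaves)
        v = heapq.heappop(leaves)
        total += dist[u, v]
        best = min(best, total)
    return best


def direct_pnn_density(patterns, v, sigma):
    """Direct-summation Parzen density over already-scaled patterns."""
    acc = 0.0
    for w in patterns:
        d2 = float(np.sum((np.asarray(v) - np.asarray(w)) ** 2))
        acc += np.exp(-d2 / (2.0 * sigma ** 2))
    return acc / len(patterns)


def ols_normal_equations(points):
    """Closed-form OLS via the 2x2 normal equations."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    A = np.array([[np.sum(x * x), np.sum(x)], [np.sum(x), len(x)]])
    rhs = np.array([np.sum(x * y), np.sum(y)])
    a, b = np.linalg.solve(A, rhs)
    return float(a), float(b)
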