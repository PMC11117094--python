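"""Independent brute-force oracles used only by the test suite.

The BROJA unique-information program over a 2x2x2 alphabet has a
two-dimensional feasible polytope: within each target slice z the 2x2
source table has fixed row and column sums, leaving one free cell per
slice. The oracle minimises the conditional mutual information by
exhaustive grid search over that rectangle with iterative refinement --
no shared code with the package's convex-program implementation.
"""

from __future__ import annotations

import numpy as np
from scipy.special import xlogy

_LN2 = np.log(2.0)


def _h(p: np.ndarray) -> np.ndarray:
    """Entropy in bits along the last axis of a stack of distributions."""
    return -xlogy(p, p).sum(axis=-1) / _LN2


def _assemble(p: np.ndarray, t0: np.ndarray, t1: np.ndarray) -> np.ndarray:
    """Joint tables q[..., x, y, z] from the per-slice free cells t_z = q(0,0,z)."""
    p_xz = p.sum(axis=1)
    p_yz = p.sum(axis=0)
    p_z = p.sum(axis=(0, 1))
    q = np.empty(t0.shape + (2, 2, 2))
    for z, t in ((0, t0), (1, t1)):
        q[..., 0, 0, z] = t
        q[..., 0, 1, z] = p_xz[0, z] - t
        q[..., 1, 0, z] = p_yz[0, z] - t
        q[..., 1, 1, z] = p_z[z] - p_xz[0, z] - p_yz[0, z] + t
    return q


def _slice_bounds(p: np.ndarray, z: int) -> tuple[float, float]:
    p_xz = p.sum(axis=1)
    p_yz = p.sum(axis=0)
    p_z = p.sum(axis=(0, 1))
    lo = max(0.0, p_xz[0, z] + p_yz[0, z] - p_z[z])
    hi = min(p_xz[0, z], p_yz[0, z])
    return lo, hi


def _cmi_xz_given_y_bits(q: np.ndarray) -> np.ndarray:
    """I(X;Z|Y) = H(X,Y) + H(Y,Z) - H(Y) - H(X,Y,Z), vectorised over leading axes."""
    n = q.shape[:-3]
    h_xy = _h(q.sum(axis=-1).reshape(n + (4,)))
    h_yz = _h(q.sum(axis=-3).reshape(n + (4,)))
    h_y = _h(q.sum(axis=(-3, -1)).reshape(n + (2,)))
    h_xyz = _h(q.reshape(n + (8,)))
    return h_xy + h_yz - h_y - h_xyz


def _min_cmi(p: np.ndarray, swap_sources: bool, steps: int = 61, rounds: int = 4) -> float:
    """Grid-refined minimum of I(X;Z|Y) (or I(Y;Z|X)) over the polytope."""
    work = np.swapaxes(p, 0, 1) if swap_sources else p
    lo0, hi0 = _slice_bounds(work, 0)
    lo1, hi1 = _slice_bounds(work, 1)
    best = np.inf
    for _ in range(rounds):
        g0 = np.linspace(lo0, hi0, steps)
        g1 = np.linspace(lo1, hi1, steps)
        t0, t1 = np.meshgrid(g0, g1, indexing="ij")
        q = np.clip(_assemble(work, t0, t1), 0.0, None)
        vals = _cmi_xz_given_y_bits(q)
        idx = np.unravel_index(np.argmin(vals), vals.shape)
        best = float(vals[idx])
        w0 = (hi0 - lo0) / (steps - 1) if steps > 1 else 0.0
        w1 = (hi1 - lo1) / (steps - 1) if steps > 1 else 0.0
        b0, b1 = g0[idx[0]], g1[idx[1]]
        blo0, bhi0 = _slice_bounds(work, 0)
        blo1, bhi1 = _slice_bounds(work, 1)
        lo0, hi0 = max(blo0, b0 - 2 * w0), min(bhi0, b0 + 2 * w0)
        lo1, hi1 = max(blo1, b1 - 2 * w1), min(bhi1, b1 + 2 * w1)
    return best


def _mi_bits(joint: np.ndarray) -> float:
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    return float(_h(pa.ravel()) + _h(pb.ravel()) - _h(joint.ravel()))


def broja_bruteforce_2x2x2(p: np.ndarray) -> dict[str, float]:
    """All four BROJA atoms of a 2x2x2 pmf by polytope grid search."""
    p = np.asarray(p, dtype=float)
    assert p.shape == (2, 2, 2)
    unq_x = _min_cmi(p, swap_sources=False)
    unq_y = _min_cmi(p, swap_sources=True)
    i_xz = _mi_bits(p.sum(axis=1))
    i_yz = _mi_bits(p.sum(axis=0))
    i_xyz = _mi_bits(p.reshape(4, 2))
    red = i_xz - unq_x
    syn = i_xyz - unq_x - unq_y - red
    return {"unq_x": unq_x, "unq_y": unq_y, "red": red, "syn": syn}
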