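"""Information-theoretic tripartite measures.

Discrete machinery operates on an exact or empirical joint probability
table over a finite three-variable alphabet. Two partial information
decompositions are provided, both in bits and both conserving the joint
mutual information I(XY:Z):

* **MMI** (minimal mutual information): redundancy is defined as
  ``min(I(X:Z), I(Y:Z))``; unique atoms are the excesses of the
  pairwise informations over the redundancy and synergy is the
  remainder of I(XY:Z). A continuous variant applies the same
  combination rules to Kraskov-type k-nearest-neighbour (KSG) estimates
  of the three mutual informations.

* **BROJA**: the unique information of X is the minimum of the
  conditional mutual information I_Q(X:Z|Y) over all joint laws Q that
  preserve the pairwise (X,Z) and (Y,Z) marginals of the data. This is
  a convex program over a marginal polytope; it is solved here over the
  polytope's free directions with analytic gradients.

The MMI definition is valid when redundancy depends only on the
pairwise source-target marginals, which holds for the corner-case
simulation models this package targets; no general-case guard is
possible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import linalg, optimize
from scipy.spatial import cKDTree
from scipy.special import digamma, xlogy

from .sim_models import (
    GroundTruthModel,
    NoiseFractions,
    TripletSample,
    VariableKind,
    discrete_alphabet_sizes,
)

__all__ = [
    "EstimationError",
    "JointPMF",
    "PIDAtoms",
    "PIDEstimator",
    "empirical_pmf",
    "exact_pmf",
    "shannon_mi",
    "mmi_pid_discrete",
    "broja_pid_discrete",
    "ksg_mi",
    "mmi_pid_continuous",
]

_LN2 = np.log(2.0)


class EstimationError(RuntimeError):
    """An estimator failed to produce a trustworthy value."""


class PIDEstimator(str, Enum):
    mmi_discrete = "mmi_discrete"
    mmi_continuous = "mmi_continuous"
    broja = "broja"


@dataclass(frozen=True)
class PIDAtoms:
    """Four information atoms (bits) plus their joint-information total."""

    unq_x: float
    unq_y: float
    red: float
    syn: float
    total_mi: float
    estimator: PIDEstimator

    def as_dict(self) -> dict[str, float]:
        return {
            "unq_x": self.unq_x,
            "unq_y": self.unq_y,
            "red": self.red,
            "syn": self.syn,
        }


@dataclass
class JointPMF:
    """Probability table over a finite (X, Y, Z) alphabet."""

    table: np.ndarray

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        if self.table.ndim != 3:
            raise ValueError("pmf table must be 3-dimensional (x, y, z)")
        if np.any(self.table < -1e-15):
            raise ValueError("pmf entries must be nonnegative")
        total = self.table.sum()
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"pmf sums to {total!r}, not 1")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.table.shape  # type: ignore[return-value]

    def to_json_dict(self) -> dict:
        return {"shape": list(self.shape), "probs": self.table.ravel().tolist()}

    @classmethod
    def from_json_dict(cls, d: dict) -> "JointPMF":
        return cls(np.asarray(d["probs"], dtype=float).reshape(d["shape"]))


def empirical_pmf(
    sample: TripletSample, alphabet_sizes: tuple[int, int, int] | None = None
) -> JointPMF:
    """Relative-frequency joint pmf of a discrete triplet sample.

    Alphabet sizes default to the declared model alphabet from the
    sample's metadata (not the observed support), falling back to the
    observed maximum.
    """
    if sample.kind is not VariableKind.discrete:
        raise TypeError("empirical_pmf requires a discrete sample")
    if alphabet_sizes is None:
        model = sample.meta.get("model")
        if model is not None:
            alphabet_sizes = discrete_alphabet_sizes(GroundTruthModel(model))
        else:
            alphabet_sizes = tuple(int(a.max()) + 1 for a in (sample.x, sample.y, sample.z))
    ax, ay, az = alphabet_sizes
    flat = (sample.x * ay + sample.y) * az + sample.z
    counts = np.bincount(flat, minlength=ax * ay * az).reshape(ax, ay, az)
    return JointPMF(counts / sample.n)


def exact_pmf(
    model: GroundTruthModel | str, nf: NoiseFractions | tuple = NoiseFractions()
) -> JointPMF:
    """Analytically exact joint law of the discrete observable model.

    Sums over the latent coin flips and the per-variable switching
    configurations: each observable equals its ground-truth value with
    probability ``1 - p`` and an independent fair coin otherwise. Serves
    as the infinite-data oracle for the sampled models.
    """
    model = GroundTruthModel(model)
    if not isinstance(nf, NoiseFractions):
        nf = NoiseFractions(*nf)
    ax, ay, az = discrete_alphabet_sizes(model)
    table = np.zeros((ax, ay, az))
    for tx, ty in itertools.product((0, 1), (0, 1)):
        if model is GroundTruthModel.mRed:
            gx, gy, gz = tx, tx, tx
        elif model is GroundTruthModel.mUnq:
            gx, gy, gz = tx, ty, tx
        elif model is GroundTruthModel.mXOR:
            gx, gy, gz = tx, ty, tx ^ ty
        else:  # mSum
            gx, gy, gz = tx, ty, tx + ty
        # Per-variable observation kernels under switching noise; the
        # noise coin lives on {0, 1} regardless of the target alphabet.
        kx = np.zeros(ax)
        kx[:2] += nf.p_x * 0.5
        kx[gx] += 1.0 - nf.p_x
        ky = np.zeros(ay)
        ky[:2] += nf.p_y * 0.5
        ky[gy] += 1.0 - nf.p_y
        kz = np.zeros(az)
        kz[:2] += nf.p_z * 0.5
        kz[gz] += 1.0 - nf.p_z
        table += 0.25 * np.einsum("i,j,k->ijk", kx, ky, kz)
    return JointPMF(table)


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy in bits, with 0*log(0) = 0."""
    return float(-xlogy(p, p).sum() / _LN2)


def shannon_mi(pmf: JointPMF, grouping: str) -> float:
    """Mutual information (bits) between a source grouping and the target.

    ``grouping`` is one of ``"x"``, ``"y"``, ``"xy"``, selecting
    I(X:Z), I(Y:Z) or I(XY:Z).
    """
    t = pmf.table
    p_z = t.sum(axis=(0, 1))
    if grouping == "x":
        p_a, p_az = t.sum(axis=(1, 2)), t.sum(axis=1)
    elif grouping == "y":
        p_a, p_az = t.sum(axis=(0, 2)), t.sum(axis=0)
    elif grouping == "xy":
        p_a, p_az = t.sum(axis=2), t
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return _entropy(p_a.ravel()) + _entropy(p_z) - _entropy(p_az.ravel())


def _mmi_atoms(i_xz: float, i_yz: float, i_xyz: float) -> tuple[float, float, float, float]:
    red = min(i_xz, i_yz)
    return i_xz - red, i_yz - red, red, i_xyz - i_xz - i_yz + red


def mmi_pid_discrete(pmf: JointPMF) -> PIDAtoms:
    """Minimal-mutual-information PID of a discrete joint pmf (bits)."""
    i_xz = shannon_mi(pmf, "x")
    i_yz = shannon_mi(pmf, "y")
    i_xyz = shannon_mi(pmf, "xy")
    unq_x, unq_y, red, syn = _mmi_atoms(i_xz, i_yz, i_xyz)
    return PIDAtoms(unq_x, unq_y, red, syn, i_xyz, PIDEstimator.mmi_discrete)


# ---------------------------------------------------------------------------
# BROJA unique information via convex optimisation.

def _broja_polytope(p: np.ndarray):
    """Free cells, feasible start and null-space of the marginal constraints.

    Cells whose (x, z) or (y, z) pairwise marginal is zero are forced to
    zero and removed. The strictly interior start is the
    conditional-independence point Q0(x,y,z) = p(x,z) p(y,z) / p(z).
    """
    ax, ay, az = p.shape
    p_xz = p.sum(axis=1)
    p_yz = p.sum(axis=0)
    p_z = p.sum(axis=(0, 1))

    free = [
        (x, y, z)
        for x, y, z in itertools.product(range(ax), range(ay), range(az))
        if p_xz[x, z] > 0 and p_yz[y, z] > 0
    ]
    q0 = np.array([p_xz[x, z] * p_yz[y, z] / p_z[z] for x, y, z in free])

    rows = []
    for x, z in itertools.product(range(ax), range(az)):
        if p_xz[x, z] > 0:
            rows.append([1.0 if (c[0] == x and c[2] == z) else 0.0 for c in free])
    for y, z in itertools.product(range(ay), range(az)):
        if p_yz[y, z] > 0:
            rows.append([1.0 if (c[1] == y and c[2] == z) else 0.0 for c in free])
    null = linalg.null_space(np.asarray(rows)) if rows else np.zeros((len(free), 0))
    return free, q0, null


def _cmi_xz_given_y(q: np.ndarray) -> float:
    """I(X : Z | Y) of a joint table with axes (x, y, z), in bits.

    Uses I(X;Z|Y) = H(X,Y) + H(Y,Z) - H(Y) - H(X,Y,Z).
    """
    return (
        _entropy(q.sum(axis=2).ravel())
        + _entropy(q.sum(axis=0).ravel())
        - _entropy(q.sum(axis=(0, 2)).ravel())
        - _entropy(q.ravel())
    )


def broja_pid_discrete(pmf: JointPMF, tol: float = 1e-10) -> PIDAtoms:
    """BROJA PID of a discrete joint pmf (bits).

    Minimises I_Q(XY:Z) (equivalently, either conditional mutual
    information) over joint laws Q preserving the (X,Z) and (Y,Z)
    pairwise marginals. At the optimum Q*, the unique atoms are the
    conditional mutual informations under Q*, redundancy is
    ``I(X:Z) - unq_x`` and synergy the conserved remainder of I(XY:Z).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    p = pmf.table
    shape = p.shape
    free, q0, null = _broja_polytope(p)

    def assemble(lam: np.ndarray) -> np.ndarray:
        q = np.zeros(shape)
        vals = q0 + null @ lam if null.shape[1] else q0
        for cell, v in zip(free, vals):
            q[cell] = v
        return q

    if null.shape[1] == 0:
        q_opt = assemble(np.zeros(0))
    else:
        eps = 1e-13

        def objective(lam):
            # I_Q(XY;Z) in nats up to constants; q_z is fixed on the polytope.
            q = np.clip(q0 + null @ lam, eps, None)
            full = assemble(lam)
            q_xy = np.clip(full.sum(axis=2), eps, None)
            val = float(np.sum(q * np.log(q)))
            val -= float(np.sum(xlogy(q_xy, q_xy)))
            grad_cells = np.array(
                [np.log(q[i]) - np.log(q_xy[c[0], c[1]]) for i, c in enumerate(free)]
            )
            return val, null.T @ grad_cells

        cons = (
            {
                "type": "ineq",
                "fun": lambda lam: q0 + null @ lam,
                "jac": lambda lam: null,
            },
        )
        res = optimize.minimize(
            objective,
            np.zeros(null.shape[1]),
            jac=True,
            method="SLSQP",
            constraints=cons,
            options={"ftol": tol, "maxiter": 500},
        )
        if not res.success:
            res2 = optimize.minimize(
                objective,
                np.zeros(null.shape[1]),
                jac=True,
                method="trust-constr",
                constraints=optimize.LinearConstraint(null, -q0, np.inf),
                options={"gtol": 1e-10, "xtol": 1e-12, "maxiter": 2000},
            )
            if not (res2.success or res2.status in (1, 2)):
                raise EstimationError(
                    f"BROJA optimisation failed: SLSQP {res.message!r}, "
                    f"trust-constr {res2.message!r}"
                )
            res = res2
        q_opt = np.clip(assemble(res.x), 0.0, None)
        q_opt /= q_opt.sum()

    unq_x = max(_cmi_xz_given_y(q_opt), 0.0)
    unq_y = max(_cmi_xz_given_y(np.swapaxes(q_opt, 0, 1)), 0.0)
    i_xz = shannon_mi(pmf, "x")
    i_yz = shannon_mi(pmf, "y")
    i_xyz = shannon_mi(pmf, "xy")
    red = i_xz - unq_x
    syn = i_xyz - unq_x - unq_y - red
    return PIDAtoms(unq_x, unq_y, red, syn, i_xyz, PIDEstimator.broja)


# ---------------------------------------------------------------------------
# Continuous estimation: Kraskov-Stoegbauer-Grassberger nearest neighbours.

_JITTER_SEED = 0x5EED
_JITTER_AMPLITUDE = 1e-10


def _as_matrix(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if not np.all(np.isfinite(a)):
        raise ValueError("samples must be finite")
    return a


def ksg_mi(a, b, k: int = 3) -> float:
    """KSG (algorithm 1) mutual information estimate in bits.

    Max-norm neighbourhoods; the k-th neighbour distance in the joint
    space sets the radius for strict-inequality marginal counts:
    ``psi(k) + psi(n) - <psi(n_a + 1) + psi(n_b + 1)>``. Ties are broken
    by a deterministic seeded jitter of amplitude 1e-10 times each
    column's scale, so the estimate is reproducible for given inputs.
    The estimate is returned unclipped and may be slightly negative.
    """
    a = _as_matrix(a)
    b = _as_matrix(b)
    n = len(a)
    if len(b) != n:
        raise ValueError("a and b must have equal row counts")
    if not (0 < k < n):
        raise ValueError("require 0 < k < n")

    rng = np.random.default_rng(_JITTER_SEED)
    def jitter(m):
        scale = m.std(axis=0)
        scale[scale == 0] = 1.0
        return m + rng.standard_normal(m.shape) * (_JITTER_AMPLITUDE * scale)

    a = jitter(a)
    b = jitter(b)
    joint = np.hstack([a, b])

    tree = cKDTree(joint)
    dist, _ = tree.query(joint, k=k + 1, p=np.inf)
    eps = dist[:, -1]
    # strictly-inside counts, excluding the point itself
    r = np.nextafter(eps, 0.0)
    n_a = cKDTree(a).query_ball_point(a, r=r, p=np.inf, return_length=True) - 1
    n_b = cKDTree(b).query_ball_point(b, r=r, p=np.inf, return_length=True) - 1
    mi_nats = digamma(k) + digamma(n) - np.mean(digamma(n_a + 1) + digamma(n_b + 1))
    return float(mi_nats / _LN2)


def mmi_pid_continuous(sample: TripletSample, k: int = 3) -> PIDAtoms:
    """Continuous MMI PID from KSG estimates of the three mutual informations.

    Atoms may be slightly negative from estimator noise and are reported
    unclipped. Deterministic source-target relations make differential
    mutual information diverge, so each variable must carry some noise
    (sample variance above 1e-12); apply a noise fraction of at least 1%
    to the sources when emulating noiseless models.
    """
    if sample.kind is not VariableKind.continuous:
        raise TypeError("mmi_pid_continuous requires a continuous sample")
    for name, arr in (("x", sample.x), ("y", sample.y), ("z", sample.z)):
        if np.var(np.asarray(arr, dtype=float)) <= 1e-12:
            raise ValueError(
                f"variable {name} is (near-)deterministic; the KSG estimator "
                "diverges for noiseless relations - add >= 1% noise"
            )
    x, y, z = (np.asarray(v, dtype=float) for v in (sample.x, sample.y, sample.z))
    i_xz = ksg_mi(x, z, k=k)
    i_yz = ksg_mi(y, z, k=k)
    i_xyz = ksg_mi(np.column_stack([x, y]), z, k=k)
    unq_x, unq_y, red, syn = _mmi_atoms(i_xz, i_yz, i_xyz)
    return PIDAtoms(unq_x, unq_y, red, syn, i_xyz, PIDEstimator.mmi_continuous)
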