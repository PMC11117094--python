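"""Ground-truth and observable (noisy) triplet simulators.

Four ground-truth models generate aligned triplets (X*, Y*, Z*) from
i.i.d. latent variables, each model exhibiting a single tripartite
relation in pure form:

* ``mRed``  -- redundancy: X* = Y* = Z* (a single latent copied thrice).
* ``mUnq``  -- unique information: Z* = X*, with Y* an independent latent.
* ``mXOR``  -- synergy: discrete Z* = XOR(X*, Y*); continuous Z* is the
  sign-XOR ``|T_z| * sign(X*) * sign(Y*)``, so |Z*| is half-normal and
  the sign of Z* is the product of the source signs.
* ``mSum``  -- Z* = X* + Y*; used only for validating the variance
  partitioning measure (PID ground truth for a sum is contested).

Continuous latents are standard normal; discrete latents are fair coin
flips. Observables are obtained by per-variable corruption with noise
fraction p in [0, 1]: continuous mixing ``(1-p)*signal + p*noise`` with
standard-normal noise, discrete switching to an independent fair coin
with probability p. Three single-parameter noise strategies (PureSrc,
NoisyX, Noisy) map a scalar nu onto the three per-variable fractions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GroundTruthModel",
    "VariableKind",
    "NoiseFractions",
    "NoiseStrategy",
    "TripletSample",
    "sample_ground_truth",
    "apply_noise",
    "strategy_to_fractions",
    "nominal_noise_fraction",
    "discrete_alphabet_sizes",
    "write_triplet_csv",
    "read_triplet_csv",
]


class GroundTruthModel(str, Enum):
    """The four ground-truth triplet models."""

    mRed = "mRed"
    mUnq = "mUnq"
    mXOR = "mXOR"
    mSum = "mSum"


class VariableKind(str, Enum):
    discrete = "discrete"
    continuous = "continuous"


class NoiseStrategy(str, Enum):
    """Single-parameter noise strategies.

    PureSrc: only the target Z is noisy, (0, 0, nu).
    NoisyX:  primary source X and target Z are noisy, (nu, 0, nu).
    Noisy:   all three observables are noisy, (nu, nu, nu).
    """

    PureSrc = "PureSrc"
    NoisyX = "NoisyX"
    Noisy = "Noisy"


@dataclass(frozen=True)
class NoiseFractions:
    """Per-variable noise fractions, each in [0, 1]."""

    p_x: float = 0.0
    p_y: float = 0.0
    p_z: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_x", "p_y", "p_z"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name}={p!r} outside [0, 1]")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_x, self.p_y, self.p_z)


@dataclass
class TripletSample:
    """Three aligned sample vectors: sources x, y and target z."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    kind: VariableKind
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x)
        self.y = np.asarray(self.y)
        self.z = np.asarray(self.z)
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise ValueError("x, y, z must have equal lengths")
        self.kind = VariableKind(self.kind)
        if self.kind is VariableKind.discrete:
            for arr in (self.x, self.y, self.z):
                if not np.issubdtype(arr.dtype, np.integer):
                    raise TypeError("discrete samples must be integer-coded")

    @property
    def n(self) -> int:
        return len(self.z)


def discrete_alphabet_sizes(model: GroundTruthModel) -> tuple[int, int, int]:
    """Alphabet sizes (a_x, a_y, a_z) of the discrete version of a model.

    All variables are binary except the mSum target, which lives on
    {0, 1, 2}.
    """
    model = GroundTruthModel(model)
    return (2, 2, 3) if model is GroundTruthModel.mSum else (2, 2, 2)


def _split_rng(seed: int, n_streams: int) -> list[np.random.Generator]:
    """One root seed, deterministically split into independent streams."""
    seqs = np.random.SeedSequence(seed).spawn(n_streams)
    return [np.random.default_rng(s) for s in seqs]


def sample_ground_truth(
    model: GroundTruthModel | str,
    kind: VariableKind | str,
    n: int,
    seed: int,
) -> TripletSample:
    """Draw ``n`` i.i.d. ground-truth triplets from ``model``.

    Continuous latents are N(0, 1); discrete latents are Bernoulli(0.5).
    Identical arguments produce bit-identical output.
    """
    model = GroundTruthModel(model)
    kind = VariableKind(kind)
    if n < 1:
        raise ValueError("n must be >= 1")
    (rng,) = _split_rng(seed, 1)

    if kind is VariableKind.continuous:
        t_x = rng.standard_normal(n)
        t_y = rng.standard_normal(n)
        t_z = rng.standard_normal(n)
        if model is GroundTruthModel.mRed:
            x, y, z = t_x, t_x.copy(), t_x.copy()
        elif model is GroundTruthModel.mUnq:
            x, y, z = t_x, t_y, t_x.copy()
        elif model is GroundTruthModel.mXOR:
            # sign-XOR: |Z| half-normal, sign(Z) = sign(X) * sign(Y);
            # sign(0) treated as +1 (probability-zero event).
            sx = np.where(t_x >= 0, 1.0, -1.0)
            sy = np.where(t_y >= 0, 1.0, -1.0)
            x, y, z = t_x, t_y, np.abs(t_z) * sx * sy
        else:  # mSum
            x, y, z = t_x, t_y, t_x + t_y
    else:
        t_x = rng.integers(0, 2, size=n)
        t_y = rng.integers(0, 2, size=n)
        if model is GroundTruthModel.mRed:
            x, y, z = t_x, t_x.copy(), t_x.copy()
        elif model is GroundTruthModel.mUnq:
            x, y, z = t_x, t_y, t_x.copy()
        elif model is GroundTruthModel.mXOR:
            x, y, z = t_x, t_y, np.bitwise_xor(t_x, t_y)
        else:  # mSum, target alphabet {0, 1, 2}
            x, y, z = t_x, t_y, t_x + t_y

    return TripletSample(
        x, y, z, kind, meta={"model": model.value, "kind": kind.value, "seed": seed}
    )


def apply_noise(
    gt: TripletSample, nf: NoiseFractions, seed: int
) -> TripletSample:
    """Corrupt a ground-truth triplet into observables.

    Continuous: ``obs = (1 - p) * signal + p * nu`` with nu ~ N(0, 1),
    i.e. amplitude mixing (the variance-share diagnostic is
    :func:`nominal_noise_fraction`). Discrete: each sample is replaced
    by an independent Bernoulli(0.5) draw with probability p
    (switching noise). The input is never modified.
    """
    if not isinstance(nf, NoiseFractions):
        nf = NoiseFractions(*nf)
    rng_noise, rng_switch = _split_rng(seed, 2)
    n = gt.n

    out = {}
    if gt.kind is VariableKind.continuous:
        for name, arr, p in (
            ("x", gt.x, nf.p_x),
            ("y", gt.y, nf.p_y),
            ("z", gt.z, nf.p_z),
        ):
            nu = rng_noise.standard_normal(n)
            out[name] = (1.0 - p) * arr + p * nu
    else:
        for name, arr, p in (
            ("x", gt.x, nf.p_x),
            ("y", gt.y, nf.p_y),
            ("z", gt.z, nf.p_z),
        ):
            nu = rng_noise.integers(0, 2, size=n)
            alpha = rng_switch.random(n) < p
            out[name] = np.where(alpha, nu, arr)

    meta = dict(gt.meta)
    meta.update({"p_x": nf.p_x, "p_y": nf.p_y, "p_z": nf.p_z})
    return TripletSample(out["x"], out["y"], out["z"], gt.kind, meta=meta)


def strategy_to_fractions(
    strategy: NoiseStrategy | str, nu: float
) -> NoiseFractions:
    """Map a noise strategy and its scalar parameter to per-variable fractions."""
    strategy = NoiseStrategy(strategy)
    if not (0.0 <= nu <= 1.0):
        raise ValueError(f"nu={nu!r} outside [0, 1]")
    if strategy is NoiseStrategy.PureSrc:
        return NoiseFractions(0.0, 0.0, nu)
    if strategy is NoiseStrategy.NoisyX:
        return NoiseFractions(nu, 0.0, nu)
    return NoiseFractions(nu, nu, nu)


def nominal_noise_fraction(p: float, kind: VariableKind | str) -> float:
    """Variance-share noise fraction of an observable with mixing parameter p.

    Continuous amplitude mixing ``(1-p)*signal + p*noise`` (unit
    variances) leaves a noise variance share of ``p^2 / (p^2 + (1-p)^2)``.
    For discrete switching noise the switching probability p itself is
    the noise fraction (it equals the mean of the switching variable).
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p={p!r} outside [0, 1]")
    kind = VariableKind(kind)
    if kind is VariableKind.discrete:
        return float(p)
    denom = p * p + (1.0 - p) * (1.0 - p)
    return float(p * p / denom)


def sample_observable(
    model: GroundTruthModel | str,
    kind: VariableKind | str,
    nf: NoiseFractions,
    n: int,
    seed: int,
) -> TripletSample:
    """Convenience: ground truth plus noise in one call.

    Latents and noise use independent substreams of ``seed``.
    """
    seq_gt, seq_noise = np.random.SeedSequence(seed).spawn(2)
    gt = sample_ground_truth(
        model, kind, n, seed=int(seq_gt.generate_state(1)[0] % (2**31))
    )
    return apply_noise(gt, nf, seed=int(seq_noise.generate_state(1)[0] % (2**31)))


# ---------------------------------------------------------------------------
# Triplet I/O: 3-column delimited text plus a sidecar JSON metadata record.

def write_triplet_csv(sample: TripletSample, path: str | Path, sep: str = ",") -> None:
    path = Path(path)
    df = pd.DataFrame({"x": sample.x, "y": sample.y, "z": sample.z})
    df.to_csv(path, index=False, sep=sep)
    meta = dict(sample.meta)
    meta.setdefault("kind", sample.kind.value)
    meta["n"] = sample.n
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_triplet_csv(path: str | Path, sep: str = ",") -> TripletSample:
    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    if list(df.columns) != ["x", "y", "z"]:
        raise ValueError(f"expected columns x,y,z; got {list(df.columns)}")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if "kind" in meta:
        kind = VariableKind(meta["kind"])
    else:
        kind = (
            VariableKind.discrete
            if all(np.issubdtype(df[c].dtype, np.integer) for c in df)
            else VariableKind.continuous
        )
    x, y, z = (df[c].to_numpy() for c in ("x", "y", "z"))
    if kind is VariableKind.discrete:
        x, y, z = (np.asarray(a, dtype=np.int64) for a in (x, y, z))
    return TripletSample(x, y, z, kind, meta=meta)
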