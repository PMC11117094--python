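"""Significance testing of information atoms.

Two testing routes are provided.

**Permutation testing.** The null distribution of an atom is built by
repeatedly generating a fresh model dataset and permuting it along the
target variable Z only (source correlations are preserved, which the
estimators can be sensitive to). The critical value at level alpha is
the conservative empirical upper quantile (order statistic of rank
``ceil((1 - alpha) * (m + 1))``). Significance of model data is then the
fraction of fresh datasets whose atom exceeds the critical value, with
a one-sided binomial test against alpha.

**Adjusted (conservative) testing.** Permutation nulls badly
underestimate atom values when source observables are noisy, so the
adjusted null hypothesis is composite: "the data came from *some* model
with zero true value of this atom, at *some* noise level". The critical
value is maximised over that adversarial set: for each zero-atom model
a 1-D grid search over noise fractions (the diagonal p_x = p_y = p_z
for unique atoms; both the diagonal and the sources-only line
p_x = p_y, p_z = 0 for redundancy and synergy) screens a coarse
percentile per grid point, then re-estimates the critical value with
many more resamples at the argmax. Exceeding this conservative critical
value rejects every model in the adversarial set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .registry import MeasureSpec, legal_atoms, measure_atoms
from .sim_models import (
    GroundTruthModel,
    NoiseFractions,
    TripletSample,
    VariableKind,
    sample_ground_truth,
    apply_noise,
)

__all__ = [
    "TripletGenerator",
    "TestConfig",
    "SearchConfig",
    "CriticalValue",
    "SignificanceSummary",
    "ADVERSARIAL_SETS",
    "adversarial_models",
    "permute_target",
    "upper_quantile",
    "draw_atom_values",
    "permutation_critical_value",
    "fraction_significant",
    "adversarial_line_cvs",
    "adversarial_cv_unique",
    "adversarial_cv_red_syn",
    "conservative_test",
]

LINES = ("diagonal", "sources_only")


@dataclass(frozen=True)
class TripletGenerator:
    """A (ground-truth model, kind, noise, size) sampling context."""

    model: GroundTruthModel
    kind: VariableKind
    nf: NoiseFractions
    n: int

    def __post_init__(self):
        object.__setattr__(self, "model", GroundTruthModel(self.model))
        object.__setattr__(self, "kind", VariableKind(self.kind))
        if not isinstance(self.nf, NoiseFractions):
            object.__setattr__(self, "nf", NoiseFractions(*self.nf))

    def sample(self, seed: int) -> TripletSample:
        ss = np.random.SeedSequence(seed).spawn(2)
        gt = sample_ground_truth(
            self.model, self.kind, self.n, int(ss[0].generate_state(1)[0] % 2**31)
        )
        return apply_noise(gt, self.nf, int(ss[1].generate_state(1)[0] % 2**31))


@dataclass(frozen=True)
class TestConfig:
    """Significance-testing configuration (defaults follow the study setup)."""

    alpha: float = 0.01
    n_samples: int = 10_000
    n_null: int = 10_000
    n_test: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("n_samples", "n_null", "n_test"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SearchConfig:
    """Adversarial grid-search configuration.

    The full-scale search uses 100 grid steps with 200 screening
    resamples per step and a 10,000-resample refinement at the argmax.
    ``continuous_floor`` keeps continuous searches away from zero noise,
    where differential-information estimators diverge.
    """

    grid_steps: int = 100
    screen_reps: int = 200
    refine_reps: int = 10_000
    continuous_floor: float = 0.01

    def grid(self, kind: VariableKind) -> np.ndarray:
        lo = self.continuous_floor if kind is VariableKind.continuous else 0.0
        return np.linspace(lo, 1.0, self.grid_steps)


@dataclass(frozen=True)
class CriticalValue:
    """A significance threshold with its provenance and context."""

    value: float
    provenance: str  # "permutation" | "adjusted"
    spec: MeasureSpec
    model: GroundTruthModel | None = None
    kind: VariableKind | None = None
    nf: NoiseFractions | None = None
    n_samples: int = 0
    alpha: float = 0.01
    argmax_noise: NoiseFractions | None = None
    line: str | None = None


@dataclass(frozen=True)
class SignificanceSummary:
    fraction_significant: float
    n_test: int
    binomial_p: float
    above_chance: bool


# Adversarial sets: ground-truth models with zero true value of each atom.
# mSum enters only for the variance-partitioning measure (for which the sum
# model has purely unique ground truth); PID measures never see mSum.
_ZERO_ATOM_MODELS = {
    "unq_x": (GroundTruthModel.mRed, GroundTruthModel.mXOR),
    "unq_y": (GroundTruthModel.mRed, GroundTruthModel.mUnq, GroundTruthModel.mXOR),
    "red": (GroundTruthModel.mUnq, GroundTruthModel.mXOR),
    "syn": (GroundTruthModel.mRed, GroundTruthModel.mUnq),
}

ADVERSARIAL_SETS: dict[tuple[str, str], tuple[GroundTruthModel, ...]] = {}
for _measure in ("pcorr", "vp", "mmi_discrete", "mmi_continuous", "broja"):
    for _atom in legal_atoms(_measure):
        models = _ZERO_ATOM_MODELS[_atom]
        if _measure == "vp" and _atom in ("red", "syn"):
            models = models + (GroundTruthModel.mSum,)
        ADVERSARIAL_SETS[(_measure, _atom)] = models


def adversarial_models(spec: MeasureSpec) -> tuple[GroundTruthModel, ...]:
    """Zero-atom (adversarial) ground-truth models for a measure/atom pair."""
    return ADVERSARIAL_SETS[(spec.measure, spec.atom)]


def permute_target(sample: TripletSample, rng: np.random.Generator) -> TripletSample:
    """Uniformly permute the target z, leaving the sources untouched."""
    if sample.n < 2:
        raise ValueError("need n >= 2 to permute")
    return TripletSample(
        sample.x, sample.y, sample.z[rng.permutation(sample.n)],
        sample.kind, meta=dict(sample.meta),
    )


def upper_quantile(values: np.ndarray, alpha: float) -> float:
    """Conservative empirical (1 - alpha) upper quantile.

    Order statistic of rank ``ceil((1 - alpha) * (m + 1))``, capped at m.
    """
    values = np.sort(np.asarray(values, dtype=float))
    m = len(values)
    rank = min(math.ceil((1.0 - alpha) * (m + 1)), m)
    return float(values[rank - 1])


# Fixed stream labels so null, test and search draws are independent.
_STREAM_NULL, _STREAM_TEST, _STREAM_SEARCH, _STREAM_PERM = 11, 23, 37, 53


def _draw_seed(root: int, stream: int, i: int) -> int:
    return int(np.random.SeedSequence([root, stream, i]).generate_state(1)[0] % 2**31)


def draw_atom_values(
    measure: str,
    gen: TripletGenerator,
    n_draws: int,
    seed: int,
    stream: int = _STREAM_NULL,
    permute: bool = False,
    spec: MeasureSpec | None = None,
) -> dict[str, np.ndarray]:
    """Atom values over ``n_draws`` fresh datasets (optionally target-permuted).

    Each draw generates a new dataset from the model; in permutation
    mode its target is then shuffled before the measure is computed
    (fresh-dataset-per-permutation is the default null-generation mode;
    see :func:`permutation_critical_value` for the fixed-dataset mode).
    All atoms of the measure are computed at once so several atoms can
    be tested from a single pass.
    """
    out: dict[str, list[float]] = {}
    for i in range(n_draws):
        sample = gen.sample(_draw_seed(seed, stream, i))
        if permute:
            rng = np.random.default_rng(_draw_seed(seed, _STREAM_PERM, i))
            sample = permute_target(sample, rng)
        atoms = measure_atoms(measure, sample, spec)
        for k, v in atoms.items():
            out.setdefault(k, []).append(v)
    return {k: np.asarray(v) for k, v in out.items()}


def permutation_critical_value(
    spec: MeasureSpec,
    gen: TripletGenerator,
    cfg: TestConfig,
    mode: str = "fresh",
) -> CriticalValue:
    """Permutation-test critical value for one measure/atom in a context.

    ``mode="fresh"`` (default) draws a new model dataset for every
    permutation; ``mode="fixed"`` permutes a single dataset ``n_null``
    times. The critical value is re-estimated per (noise, data-size)
    context, since the null shifts with both.
    """
    if cfg.n_null * cfg.alpha < 5:
        warnings.warn(
            "n_null * alpha < 5: the tail quantile is unstable", stacklevel=2
        )
    if mode == "fresh":
        values = draw_atom_values(
            spec.measure, gen, cfg.n_null, cfg.seed, _STREAM_NULL, permute=True,
            spec=spec,
        )[spec.atom]
    elif mode == "fixed":
        base = gen.sample(_draw_seed(cfg.seed, _STREAM_NULL, 0))
        vals = []
        for i in range(cfg.n_null):
            rng = np.random.default_rng(_draw_seed(cfg.seed, _STREAM_PERM, i))
            vals.append(
                measure_atoms(spec.measure, permute_target(base, rng), spec)[spec.atom]
            )
        values = np.asarray(vals)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return CriticalValue(
        value=upper_quantile(values, cfg.alpha),
        provenance="permutation",
        spec=spec,
        model=gen.model,
        kind=gen.kind,
        nf=gen.nf,
        n_samples=gen.n,
        alpha=cfg.alpha,
    )


def fraction_significant(
    spec: MeasureSpec,
    gen: TripletGenerator,
    cv: CriticalValue,
    cfg: TestConfig,
) -> SignificanceSummary:
    """Fraction of fresh model datasets whose atom strictly exceeds ``cv``.

    The count is compared against Binomial(n_test, alpha) with a
    one-sided (greater) test; ``above_chance`` flags rejection at 0.01.
    """
    values = draw_atom_values(
        spec.measure, gen, cfg.n_test, cfg.seed, _STREAM_TEST, spec=spec
    )[spec.atom]
    count = int(np.sum(values > cv.value))
    test = stats.binomtest(count, cfg.n_test, cfg.alpha, alternative="greater")
    return SignificanceSummary(
        fraction_significant=count / cfg.n_test,
        n_test=cfg.n_test,
        binomial_p=float(test.pvalue),
        above_chance=bool(test.pvalue < 0.01),
    )


def _line_fractions(line: str, nu: float) -> NoiseFractions:
    if line == "diagonal":
        return NoiseFractions(nu, nu, nu)
    if line == "sources_only":
        return NoiseFractions(nu, nu, 0.0)
    raise ValueError(f"unknown search line {line!r}")


def adversarial_line_cvs(
    measure: str,
    model: GroundTruthModel | str,
    kind: VariableKind | str,
    line: str,
    cfg: TestConfig,
    search: SearchConfig,
    atoms: tuple[str, ...] | None = None,
    spec: MeasureSpec | None = None,
) -> dict[str, tuple[float, float]]:
    """Grid-search one noise line for one adversarial model, all atoms at once.

    Returns ``{atom: (refined_cv, argmax_nu)}``. At every grid step the
    model is resampled ``screen_reps`` times and the upper-alpha
    percentile screened per atom; the argmax step is then resampled
    ``refine_reps`` times for the precise critical value. Continuous
    searches are floored at ``search.continuous_floor``: on the
    sources-only line the target keeps zero noise only for discrete
    data, while for continuous data all three variables get at least
    the floor (the estimators diverge otherwise).
    """
    model = GroundTruthModel(model)
    kind = VariableKind(kind)
    atoms = atoms or legal_atoms(measure)
    grid = search.grid(kind)
    floor = search.continuous_floor if kind is VariableKind.continuous else 0.0

    def nf_at(nu: float) -> NoiseFractions:
        nf = _line_fractions(line, nu)
        if floor:
            nf = NoiseFractions(*(max(p, floor) for p in nf.as_tuple()))
        return nf

    screen = {a: np.empty(len(grid)) for a in atoms}
    for j, nu in enumerate(grid):
        gen = TripletGenerator(model, kind, nf_at(nu), cfg.n_samples)
        vals = draw_atom_values(
            measure, gen, search.screen_reps, cfg.seed, _STREAM_SEARCH, spec=spec
        )
        for a in atoms:
            screen[a][j] = upper_quantile(vals[a], cfg.alpha)

    # refine once per distinct argmax step, shared across atoms
    argmax_step = {a: int(np.argmax(screen[a])) for a in atoms}
    refined_by_step: dict[int, dict[str, float]] = {}
    for step in sorted(set(argmax_step.values())):
        gen = TripletGenerator(model, kind, nf_at(grid[step]), cfg.n_samples)
        vals = draw_atom_values(
            measure, gen, search.refine_reps, cfg.seed, _STREAM_SEARCH + step + 1,
            spec=spec,
        )
        refined_by_step[step] = {a: upper_quantile(vals[a], cfg.alpha) for a in atoms}

    return {
        a: (refined_by_step[argmax_step[a]][a], float(grid[argmax_step[a]]))
        for a in atoms
    }


def adversarial_cv_unique(
    spec: MeasureSpec,
    adversarial_model: GroundTruthModel | str,
    kind: VariableKind | str,
    cfg: TestConfig,
    search: SearchConfig | None = None,
) -> CriticalValue:
    """Adjusted critical value for a unique atom under one adversarial model.

    The search runs along the diagonal p_x = p_y = p_z (the fully noisy
    strategy); with asymmetric source noise the spurious unique atom is
    unbounded and the estimation problem is not identifiable.
    """
    if spec.atom not in ("unq_x", "unq_y"):
        raise ValueError("adversarial_cv_unique handles unique atoms only")
    search = search or SearchConfig()
    kind = VariableKind(kind)
    cvs = adversarial_line_cvs(
        spec.measure, adversarial_model, kind, "diagonal", cfg, search,
        atoms=(spec.atom,), spec=spec,
    )
    value, nu = cvs[spec.atom]
    return CriticalValue(
        value=value,
        provenance="adjusted",
        spec=spec,
        model=GroundTruthModel(adversarial_model),
        kind=kind,
        n_samples=cfg.n_samples,
        alpha=cfg.alpha,
        argmax_noise=_line_fractions("diagonal", nu),
        line="diagonal",
    )


def adversarial_cv_red_syn(
    spec: MeasureSpec,
    models: tuple[GroundTruthModel, ...] | None = None,
    kind: VariableKind | str = VariableKind.discrete,
    cfg: TestConfig = TestConfig(),
    search: SearchConfig | None = None,
) -> CriticalValue:
    """Adjusted critical value for a redundancy or synergy atom.

    Both candidate 1-D noise lines (diagonal, and sources-only with a
    noiseless target) are searched for every adversarial model, and the
    maximum refined critical value is returned -- strictly more
    conservative than picking one line by inspection of the noise
    dependence pattern.
    """
    if spec.atom not in ("red", "syn"):
        raise ValueError("adversarial_cv_red_syn handles red/syn atoms only")
    if models is None:
        models = adversarial_models(spec)
    if not models:
        raise ValueError("empty adversarial model set")
    search = search or SearchConfig()
    kind = VariableKind(kind)

    best: CriticalValue | None = None
    for model in models:
        for line in LINES:
            cvs = adversarial_line_cvs(
                spec.measure, model, kind, line, cfg, search,
                atoms=(spec.atom,), spec=spec,
            )
            value, nu = cvs[spec.atom]
            if best is None or value > best.value:
                best = CriticalValue(
                    value=value,
                    provenance="adjusted",
                    spec=spec,
                    model=GroundTruthModel(model),
                    kind=kind,
                    n_samples=cfg.n_samples,
                    alpha=cfg.alpha,
                    argmax_noise=_line_fractions(line, nu),
                    line=line,
                )
    assert best is not None
    return best


def conservative_test(atom_value: float, cv: CriticalValue) -> bool:
    """True iff the atom strictly exceeds the conservative critical value.

    Rejection means rejecting *every* model in the adversarial set.
    """
    if not (np.isfinite(atom_value) and np.isfinite(cv.value)):
        raise ValueError("atom value and critical value must be finite")
    return bool(atom_value > cv.value)
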