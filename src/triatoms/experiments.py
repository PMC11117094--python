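"""Config-driven sweep engine reproducing the simulation study.

Sweeps cross ground-truth models, variable kinds, noise strategies and
measures over a noise-fraction grid (or a data-size grid), permutation-
and/or conservatively testing every atom at every grid point, and emit
tidy one-row-per-atom tables. Two named profiles bundle the problem
sizes: ``paper`` (10,000 null and test repetitions) and ``desk`` (500
repetitions and a coarsened adversarial search) for interactive runs,
with correspondingly wider Monte-Carlo error bars.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .registry import MEASURES, MeasureSpec, legal_atoms, measure_kinds
from .sim_models import (
    GroundTruthModel,
    NoiseStrategy,
    VariableKind,
    strategy_to_fractions,
)
from .testing import (
    ADVERSARIAL_SETS,
    LINES,
    CriticalValue,
    SearchConfig,
    TestConfig,
    TripletGenerator,
    adversarial_cv_red_syn,
    adversarial_cv_unique,
    adversarial_line_cvs,
    draw_atom_values,
    upper_quantile,
    _STREAM_TEST,
)

__all__ = [
    "SweepSpec",
    "PROFILES",
    "default_noise_grid",
    "run_noise_sweep",
    "run_size_sweep",
    "summarize_sketch",
    "build_cv_table",
    "run_manifest",
]

SWEEP_COLUMNS = [
    "model", "kind", "strategy", "nu", "p_x", "p_y", "p_z", "n",
    "measure", "atom", "atom_mean", "atom_q01", "atom_q99",
    "cv_perm", "cv_adj", "fraction_sig_perm", "fraction_sig_adj",
    "binomial_p", "seed", "error",
]

PROFILES = {
    "paper": {
        "cfg": TestConfig(),
        "search": SearchConfig(),
    },
    "desk": {
        "cfg": TestConfig(n_null=500, n_test=500),
        "search": SearchConfig(grid_steps=20, screen_reps=50, refine_reps=1000),
    },
}


def default_noise_grid() -> list[float]:
    """Zero plus 30 log-spaced points on [0.001, 1]."""
    return [0.0] + list(np.round(np.logspace(-3, 0, 30), 6))


@dataclass
class SweepSpec:
    """Declarative description of one sweep."""

    models: list = field(default_factory=lambda: [m.value for m in GroundTruthModel])
    kinds: list = field(default_factory=lambda: ["discrete", "continuous"])
    strategies: list = field(default_factory=lambda: ["PureSrc", "NoisyX", "Noisy"])
    measures: list = field(
        default_factory=lambda: ["pcorr", "vp", "mmi_discrete", "mmi_continuous", "broja"]
    )
    noise_grid: list = field(default_factory=default_noise_grid)
    size_grid: list = field(default_factory=lambda: [100, 300, 1000, 3000, 10000])
    cfg: TestConfig = field(default_factory=TestConfig)
    search: SearchConfig = field(default_factory=SearchConfig)
    testing_mode: str = "permutation"  # "permutation" | "adjusted" | "both"

    def __post_init__(self) -> None:
        self.models = [GroundTruthModel(m) for m in self.models]
        self.kinds = [VariableKind(k) for k in self.kinds]
        self.strategies = [NoiseStrategy(s) for s in self.strategies]
        if isinstance(self.cfg, dict):
            self.cfg = TestConfig(**self.cfg)
        if isinstance(self.search, dict):
            self.search = SearchConfig(**self.search)
        if not self.noise_grid or not self.size_grid:
            raise ValueError("noise and size grids must be nonempty")
        if self.testing_mode not in ("permutation", "adjusted", "both"):
            raise ValueError(f"unknown testing_mode {self.testing_mode!r}")
        for m in self.measures:
            if m not in MEASURES:
                raise ValueError(f"unknown measure {m!r}")
        for nu in self.noise_grid:
            if not (0.0 <= nu <= 1.0):
                raise ValueError("noise grid values must lie in [0, 1]")
        for n in self.size_grid:
            if n < 1:
                raise ValueError("size grid values must be positive")

    # -- config files -------------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "SweepSpec":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["models"] = [m.value for m in self.models]
        d["kinds"] = [k.value for k in self.kinds]
        d["strategies"] = [s.value for s in self.strategies]
        return d


def _combos(spec: SweepSpec):
    """Legal (model, kind, strategy, measure) combinations.

    PID measures are never paired with mSum (contested ground truth);
    measures incompatible with a kind are skipped.
    """
    for model in spec.models:
        for kind in spec.kinds:
            for measure in spec.measures:
                if kind not in measure_kinds(measure):
                    continue
                if model is GroundTruthModel.mSum and measure in (
                    "mmi_discrete", "mmi_continuous", "broja"
                ):
                    continue
                for strategy in spec.strategies:
                    yield model, kind, strategy, measure


def _adjusted_cvs(
    measure: str, kind: VariableKind, cfg: TestConfig, search: SearchConfig
) -> dict[str, CriticalValue]:
    """Operative conservative CV per atom of a measure (noise-independent)."""
    out = {}
    for atom in legal_atoms(measure):
        spec = MeasureSpec(measure, atom)
        models = ADVERSARIAL_SETS[(measure, atom)]
        if atom in ("unq_x", "unq_y"):
            best = None
            for model in models:
                cv = adversarial_cv_unique(spec, model, kind, cfg, search)
                if best is None or cv.value > best.value:
                    best = cv
            out[atom] = best
        else:
            out[atom] = adversarial_cv_red_syn(spec, models, kind, cfg, search)
    return out


def _flush(rows: list[dict], out_path: Path | None, header_written: bool) -> bool:
    if out_path is None or not rows:
        return header_written
    df = pd.DataFrame(rows, columns=SWEEP_COLUMNS)
    df.to_csv(out_path, mode="a", header=not header_written, index=False)
    return True


def _sweep(spec: SweepSpec, points, out_path: str | Path | None) -> pd.DataFrame:
    """Shared engine for noise and size sweeps.

    ``points`` yields (nu, n) pairs. Rows are flushed to ``out_path``
    incrementally so interrupted sweeps keep completed points.
    """
    out_path = Path(out_path) if out_path is not None else None
    if out_path is not None and out_path.exists():
        out_path.unlink()
    cfg, search = spec.cfg, spec.search
    all_rows: list[dict] = []
    header_written = False
    adjusted_cache: dict[tuple, dict[str, CriticalValue]] = {}

    for model, kind, strategy, measure in _combos(spec):
        cv_adj: dict[str, CriticalValue] = {}
        if spec.testing_mode in ("adjusted", "both"):
            key = (measure, kind, cfg.n_samples)
            if key not in adjusted_cache:
                adjusted_cache[key] = _adjusted_cvs(measure, kind, cfg, search)
            cv_adj = adjusted_cache[key]

        for nu, n in points:
            nf = strategy_to_fractions(strategy, nu)
            gen = TripletGenerator(model, kind, nf, n)
            point_cfg = replace(cfg, n_samples=n)
            rows = []
            try:
                null_vals = test_vals = None
                if spec.testing_mode in ("permutation", "both"):
                    null_vals = draw_atom_values(
                        measure, gen, point_cfg.n_null, point_cfg.seed, permute=True
                    )
                test_vals = draw_atom_values(
                    measure, gen, point_cfg.n_test, point_cfg.seed,
                    stream=_STREAM_TEST,
                )
                for atom in legal_atoms(measure):
                    vals = test_vals[atom]
                    row = {
                        "model": model.value, "kind": kind.value,
                        "strategy": strategy.value, "nu": nu,
                        "p_x": nf.p_x, "p_y": nf.p_y, "p_z": nf.p_z, "n": n,
                        "measure": measure, "atom": atom,
                        "atom_mean": float(vals.mean()),
                        "atom_q01": float(np.quantile(vals, 0.01)),
                        "atom_q99": float(np.quantile(vals, 0.99)),
                        "cv_perm": np.nan, "cv_adj": np.nan,
                        "fraction_sig_perm": np.nan, "fraction_sig_adj": np.nan,
                        "binomial_p": np.nan,
                        "seed": point_cfg.seed, "error": "",
                    }
                    if null_vals is not None:
                        cvp = upper_quantile(null_vals[atom], point_cfg.alpha)
                        count = int(np.sum(vals > cvp))
                        row["cv_perm"] = cvp
                        row["fraction_sig_perm"] = count / len(vals)
                        row["binomial_p"] = float(
                            stats.binomtest(
                                count, len(vals), point_cfg.alpha, "greater"
                            ).pvalue
                        )
                    if atom in cv_adj:
                        cva = cv_adj[atom]
                        row["cv_adj"] = cva.value
                        row["fraction_sig_adj"] = float(np.mean(vals > cva.value))
                    rows.append(row)
            except Exception as exc:  # sweep continues past per-point failures
                rows = [{
                    "model": model.value, "kind": kind.value,
                    "strategy": strategy.value, "nu": nu,
                    "p_x": nf.p_x, "p_y": nf.p_y, "p_z": nf.p_z, "n": n,
                    "measure": measure, "atom": atom,
                    "atom_mean": np.nan, "atom_q01": np.nan, "atom_q99": np.nan,
                    "cv_perm": np.nan, "cv_adj": np.nan,
                    "fraction_sig_perm": np.nan, "fraction_sig_adj": np.nan,
                    "binomial_p": np.nan, "seed": point_cfg.seed,
                    "error": f"{type(exc).__name__}: {exc}",
                } for atom in legal_atoms(measure)]
            all_rows.extend(rows)
            header_written = _flush(rows, out_path, header_written)

    return pd.DataFrame(all_rows, columns=SWEEP_COLUMNS)


def run_noise_sweep(
    spec: SweepSpec, out_path: str | Path | None = None
) -> pd.DataFrame:
    """Sweep the single-parameter noise fraction at fixed data size."""
    points = [(float(nu), spec.cfg.n_samples) for nu in spec.noise_grid]
    return _sweep(spec, points, out_path)


def run_size_sweep(
    spec: SweepSpec, nu: float = 0.25, out_path: str | Path | None = None
) -> pd.DataFrame:
    """Sweep the data size at a fixed noise fraction (default 0.25)."""
    points = [(float(nu), int(n)) for n in spec.size_grid]
    return _sweep(spec, points, out_path)


def summarize_sketch(rows: pd.DataFrame, nu: float) -> pd.DataFrame:
    """Significance matrix at one noise fraction.

    Rows are (measure, atom), columns ground-truth models; entries are
    the fraction of significant atoms, for the permutation and (when
    present) adjusted procedures.
    """
    sel = rows[np.isclose(rows["nu"].astype(float), nu)]
    if sel.empty:
        raise LookupError(f"no sweep rows at nu={nu!r}")
    frames = []
    for col, label in (
        ("fraction_sig_perm", "permutation"),
        ("fraction_sig_adj", "adjusted"),
    ):
        if sel[col].notna().any():
            pivot = sel.pivot_table(
                index=["measure", "atom"], columns="model", values=col,
                aggfunc="mean",
            )
            pivot.columns = pd.MultiIndex.from_product([[label], pivot.columns])
            frames.append(pivot)
    return pd.concat(frames, axis=1)


def build_cv_table(spec: SweepSpec) -> pd.DataFrame:
    """Conservative-critical-value table at fixed data size.

    One row per legal (measure, atom, kind, model): the refined adjusted
    CV with the noise point and line that produced it. CVs are computed
    for *all* legal models so biases can be compared across models;
    ``in_adversarial_set`` marks models with zero true atom, and the
    operative conservative CV (``is_operative``) is the row-wise maximum
    over that set only.
    """
    cfg, search = spec.cfg, spec.search
    records = []
    for measure in spec.measures:
        for kind in spec.kinds:
            if kind not in measure_kinds(measure):
                continue
            models = [
                m for m in spec.models
                if not (
                    m is GroundTruthModel.mSum
                    and measure in ("mmi_discrete", "mmi_continuous", "broja")
                )
            ]
            atoms = legal_atoms(measure)
            for model in models:
                per_line: dict[str, dict[str, tuple[float, float]]] = {}
                for line in LINES:
                    per_line[line] = adversarial_line_cvs(
                        measure, model, kind, line, cfg, search, atoms=atoms
                    )
                for atom in atoms:
                    lines = ("diagonal",) if atom in ("unq_x", "unq_y") else LINES
                    best_line = max(lines, key=lambda ln: per_line[ln][atom][0])
                    value, nu = per_line[best_line][atom]
                    p = (nu, nu, nu) if best_line == "diagonal" else (nu, nu, 0.0)
                    records.append({
                        "measure": measure, "atom": atom, "kind": kind.value,
                        "adversarial_model": model.value, "line": best_line,
                        "argmax_nu": nu, "p_x": p[0], "p_y": p[1], "p_z": p[2],
                        "n_samples": cfg.n_samples, "alpha": cfg.alpha,
                        "cv": value, "provenance": "adjusted",
                        "in_adversarial_set": model
                        in ADVERSARIAL_SETS[(measure, atom)],
                    })
    df = pd.DataFrame(records)
    df["is_operative"] = False
    for (measure, atom, kind), grp in df.groupby(["measure", "atom", "kind"]):
        grp_s = grp[grp["in_adversarial_set"]]
        if not grp_s.empty:
            df.loc[grp_s["cv"].idxmax(), "is_operative"] = True
    return df


def run_manifest(spec: SweepSpec, profile: str | None = None) -> dict:
    """JSON-serialisable provenance record for a sweep run."""
    cfg_dict = spec.to_dict()
    blob = json.dumps(cfg_dict, sort_keys=True).encode()
    import pandas
    import scipy

    return {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": spec.cfg.seed,
        "profile": profile,
        "versions": {
            "triatoms": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
    }
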