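"""Measure registry: uniform atom-valued interface over the four measures.

Every measure maps a triplet sample to a dict of test statistics keyed
by atom name (``unq_x``, ``unq_y``, ``red``, ``syn``). Partial
correlation exposes only the two unique atoms, reported as magnitudes
|PCorr| (relations are two-sided, so the absolute value is the natural
one-sided test statistic); all other atoms are signed values.

The registry also encodes which variable kind each measure accepts and
which (measure, ground-truth model) pairings are legal: PID measures
are never applied to the sum model, whose PID ground truth is contested.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import info_measures, linear_measures
from .sim_models import GroundTruthModel, TripletSample, VariableKind

__all__ = [
    "MEASURES",
    "MeasureSpec",
    "measure_atoms",
    "legal_atoms",
    "measure_kinds",
    "check_pairing",
]

ALL_ATOMS = ("unq_x", "unq_y", "red", "syn")


@dataclass(frozen=True)
class MeasureSpec:
    """A (measure, atom) pair with estimator parameters."""

    measure: str
    atom: str
    k: int = 3           # KSG neighbour count
    tol: float = 1e-10   # BROJA objective tolerance

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.atom not in legal_atoms(self.measure):
            raise ValueError(
                f"atom {self.atom!r} is not exposed by measure {self.measure!r}"
            )


def _pcorr(sample: TripletSample, spec) -> dict[str, float]:
    x, y, z = sample.x, sample.y, sample.z
    return {
        "unq_x": abs(linear_measures.partial_correlation(x, y, z)),
        "unq_y": abs(linear_measures.partial_correlation(y, x, z)),
    }


def _vp(sample: TripletSample, spec) -> dict[str, float]:
    return linear_measures.vp_atoms(sample.x, sample.y, sample.z).as_dict()


def _mmi_discrete(sample: TripletSample, spec) -> dict[str, float]:
    return info_measures.mmi_pid_discrete(info_measures.empirical_pmf(sample)).as_dict()


def _broja(sample: TripletSample, spec) -> dict[str, float]:
    pmf = info_measures.empirical_pmf(sample)
    return info_measures.broja_pid_discrete(pmf, tol=spec.tol if spec else 1e-10).as_dict()


def _mmi_continuous(sample: TripletSample, spec) -> dict[str, float]:
    k = spec.k if spec else 3
    return info_measures.mmi_pid_continuous(sample, k=k).as_dict()


@dataclass(frozen=True)
class _MeasureEntry:
    fn: object
    atoms: tuple[str, ...]
    kinds: tuple[VariableKind, ...]


_BOTH = (VariableKind.discrete, VariableKind.continuous)

MEASURES: dict[str, _MeasureEntry] = {
    "pcorr": _MeasureEntry(_pcorr, ("unq_x", "unq_y"), _BOTH),
    "vp": _MeasureEntry(_vp, ALL_ATOMS, _BOTH),
    "mmi_discrete": _MeasureEntry(_mmi_discrete, ALL_ATOMS, (VariableKind.discrete,)),
    "broja": _MeasureEntry(_broja, ALL_ATOMS, (VariableKind.discrete,)),
    "mmi_continuous": _MeasureEntry(
        _mmi_continuous, ALL_ATOMS, (VariableKind.continuous,)
    ),
}

_PID_MEASURES = frozenset({"mmi_discrete", "mmi_continuous", "broja"})


def legal_atoms(measure: str) -> tuple[str, ...]:
    return MEASURES[measure].atoms


def measure_kinds(measure: str) -> tuple[VariableKind, ...]:
    return MEASURES[measure].kinds


def check_pairing(measure: str, model: GroundTruthModel | str) -> None:
    """Reject illegal (measure, model) pairings (PID on the sum model)."""
    model = GroundTruthModel(model)
    if measure in _PID_MEASURES and model is GroundTruthModel.mSum:
        raise ValueError(
            f"measure {measure!r} is not applied to mSum: its PID ground "
            "truth is contested"
        )


def measure_atoms(
    measure: str, sample: TripletSample, spec: MeasureSpec | None = None
) -> dict[str, float]:
    """All atoms of ``measure`` for one triplet sample."""
    entry = MEASURES[measure]
    if sample.kind not in entry.kinds:
        raise TypeError(
            f"measure {measure!r} does not accept {sample.kind.value} samples"
        )
    return entry.fn(sample, spec)
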