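"""Discrete pmf machinery, Shannon/PID quantities, KSG estimation."""

import numpy as np
import pytest

from oracles import broja_bruteforce_2x2x2
from triatoms.info_measures import (
    JointPMF,
    PIDEstimator,
    broja_pid_discrete,
    empirical_pmf,
    exact_pmf,
    ksg_mi,
    mmi_pid_continuous,
    mmi_pid_discrete,
    shannon_mi,
)
from triatoms.sim_models import (
    NoiseFractions,
    TripletSample,
    apply_noise,
    sample_ground_truth,
    sample_observable,
)

CORNERS = [
    ("mXOR", (0.0, 0.0, 0.0, 1.0)),
    ("mRed", (0.0, 0.0, 1.0, 0.0)),
    ("mUnq", (1.0, 0.0, 0.0, 0.0)),
]


def _and_gate_pmf() -> JointPMF:
    t = np.zeros((2, 2, 2))
    for x in range(2):
        for y in range(2):
            t[x, y, x & y] = 0.25
    return JointPMF(t)


def test_pmf_validation():
    with pytest.raises(ValueError):
        JointPMF(np.full((2, 2, 2), 0.2))
    with pytest.raises(ValueError):
        JointPMF(np.ones((2, 2)) / 4)


def test_pmf_json_roundtrip():
    pmf = exact_pmf("mSum", NoiseFractions(0.1, 0.2, 0.3))
    back = JointPMF.from_json_dict(pmf.to_json_dict())
    np.testing.assert_allclose(pmf.table, back.table)


def test_empirical_pmf_delta_and_normalisation():
    zeros = np.zeros(40, dtype=np.int64)
    s = TripletSample(zeros, zeros, zeros, "discrete", meta={"model": "mRed"})
    pmf = empirical_pmf(s)
    assert pmf.table[0, 0, 0] == 1.0
    assert pmf.table.sum() == pytest.approx(1.0)


def test_empirical_pmf_xor_support():
    x = np.array([0, 0, 1, 1] * 10)
    y = np.array([0, 1, 0, 1] * 10)
    s = TripletSample(x, y, x ^ y, "discrete", meta={"model": "mXOR"})
    pmf = empirical_pmf(s)
    assert pmf.table[0, 0, 0] == pytest.approx(0.25)
    assert pmf.table[0, 0, 1] == 0.0


def test_empirical_pmf_rejects_continuous():
    s = sample_ground_truth("mRed", "continuous", 10, seed=0)
    with pytest.raises(TypeError):
        empirical_pmf(s)


def test_exact_pmf_noiseless_corners():
    xor = exact_pmf("mXOR").table
    for x in range(2):
        for y in range(2):
            assert xor[x, y, x ^ y] == pytest.approx(0.25)
    assert xor.sum() == pytest.approx(1.0)

    red = exact_pmf("mRed").table
    assert red[0, 0, 0] == pytest.approx(0.5)
    assert red[1, 1, 1] == pytest.approx(0.5)

    uniform = exact_pmf("mRed", NoiseFractions(1, 1, 1)).table
    np.testing.assert_allclose(uniform, 1 / 8)


def test_exact_pmf_matches_empirical_frequencies():
    # total-variation distance shrinks to sampling noise at n = 10,000
    for model, nf in [
        ("mRed", NoiseFractions(0.3, 0.3, 0.3)),
        ("mXOR", NoiseFractions(0.1, 0.0, 0.5)),
        ("mSum", NoiseFractions(0.0, 0.2, 0.4)),
    ]:
        emp = empirical_pmf(sample_observable(model, "discrete", nf, 10_000, seed=3))
        tv = 0.5 * np.abs(emp.table - exact_pmf(model, nf).table).sum()
        assert tv <= 0.02


def test_shannon_mi_known_values():
    uniform = JointPMF(np.full((2, 2, 2), 1 / 8))
    assert shannon_mi(uniform, "x") == pytest.approx(0.0, abs=1e-12)
    assert shannon_mi(uniform, "xy") == pytest.approx(0.0, abs=1e-12)

    copy = exact_pmf("mRed")
    assert shannon_mi(copy, "x") == pytest.approx(1.0)

    assert shannon_mi(exact_pmf("mXOR"), "xy") == pytest.approx(1.0)
    assert shannon_mi(exact_pmf("mXOR"), "x") == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("model,expected", CORNERS)
def test_mmi_pid_corner_models(model, expected):
    atoms = mmi_pid_discrete(exact_pmf(model))
    got = (atoms.unq_x, atoms.unq_y, atoms.red, atoms.syn)
    np.testing.assert_allclose(got, expected, atol=1e-12)
    assert atoms.unq_x + atoms.unq_y + atoms.red + atoms.syn == pytest.approx(
        atoms.total_mi, abs=1e-12
    )


@pytest.mark.parametrize("model,expected", CORNERS)
def test_broja_agrees_with_mmi_on_corners(model, expected):
    atoms = broja_pid_discrete(exact_pmf(model))
    got = (atoms.unq_x, atoms.unq_y, atoms.red, atoms.syn)
    np.testing.assert_allclose(got, expected, atol=1e-9)


def test_broja_and_gate_matches_bruteforce():
    pmf = _and_gate_pmf()
    oracle = broja_bruteforce_2x2x2(pmf.table)
    atoms = broja_pid_discrete(pmf)
    for k, v in atoms.as_dict().items():
        assert v == pytest.approx(oracle[k], abs=1e-3)
    # the known AND-gate decomposition
    assert atoms.red == pytest.approx(0.311278, abs=1e-3)
    assert atoms.syn == pytest.approx(0.5, abs=1e-3)


def test_broja_random_pmfs_match_bruteforce(rng):
    for _ in range(5):
        p = rng.dirichlet(np.ones(8)).reshape(2, 2, 2)
        oracle = broja_bruteforce_2x2x2(p)
        atoms = broja_pid_discrete(JointPMF(p))
        for k, v in atoms.as_dict().items():
            assert v == pytest.approx(oracle[k], abs=1e-3)


def test_broja_delta_pmf_all_zero():
    t = np.zeros((2, 2, 2))
    t[1, 0, 1] = 1.0
    atoms = broja_pid_discrete(JointPMF(t))
    assert atoms.as_dict() == {"unq_x": 0.0, "unq_y": 0.0, "red": 0.0, "syn": 0.0}


def test_discrete_mmi_synergy_nonnegative_on_exact_pmfs(rng):
    # I(XY:Z) >= max(I(X:Z), I(Y:Z)) makes MMI synergy nonnegative
    for model in ("mRed", "mUnq", "mXOR", "mSum"):
        for _ in range(3):
            nf = NoiseFractions(*rng.random(3))
            atoms = mmi_pid_discrete(exact_pmf(model, nf))
            assert atoms.syn >= -1e-12


def test_ksg_independent_near_zero(rng):
    a, b = rng.standard_normal((2, 2000))
    assert abs(ksg_mi(a, b, k=3)) < 0.03


def test_ksg_bivariate_gaussian_closed_form(rng):
    n = 5000
    a = rng.standard_normal(n)
    b = 0.8 * a + 0.6 * rng.standard_normal(n)
    expected = -0.5 * np.log2(1 - 0.64)
    assert ksg_mi(a, b, k=3) == pytest.approx(expected, abs=0.05)


def test_ksg_symmetry_and_validation(rng):
    a, b = rng.standard_normal((2, 500))
    assert ksg_mi(a, b, 3) == pytest.approx(ksg_mi(b, a, 3), abs=1e-6)
    with pytest.raises(ValueError):
        ksg_mi(a, b, k=500)


def test_continuous_mmi_sign_xor_is_synergy():
    # sign(Z) carries exactly one bit about (sign X, sign Y); each source
    # alone is uninformative by sign symmetry
    # the population synergy is 1 bit; the joint KSG estimate carries a
    # finite-sample negative bias at this n, hence the loose band
    s = sample_ground_truth("mXOR", "continuous", 5000, seed=5)
    atoms = mmi_pid_continuous(s)
    assert atoms.syn == pytest.approx(1.0, abs=0.2)
    assert atoms.syn > 10 * max(abs(atoms.red), abs(atoms.unq_x), abs(atoms.unq_y))
    assert abs(atoms.red) < 0.05
    assert abs(atoms.unq_x) < 0.05
    assert atoms.estimator is PIDEstimator.mmi_continuous


def test_continuous_mmi_unique_model_with_source_noise():
    gt = sample_ground_truth("mUnq", "continuous", 5000, seed=6)
    s = apply_noise(gt, NoiseFractions(0.01, 0.01, 0.01), seed=7)
    atoms = mmi_pid_continuous(s)
    assert atoms.unq_x > 10 * abs(atoms.unq_y)
    assert abs(atoms.red) < 0.05
    # conservation holds by construction of the combination rules
    total = atoms.unq_x + atoms.unq_y + atoms.red + atoms.syn
    assert total == pytest.approx(atoms.total_mi, abs=1e-9)


def test_continuous_mmi_independent_near_zero(rng):
    x, y, z = rng.standard_normal((3, 2000))
    atoms = mmi_pid_continuous(TripletSample(x, y, z, "continuous"))
    for v in atoms.as_dict().values():
        assert abs(v) < 0.05


def test_continuous_mmi_rejects_degenerate_variance():
    s = sample_ground_truth("mRed", "continuous", 500, seed=8)
    s.z = np.zeros(500)
    with pytest.raises(ValueError, match="noise"):
        mmi_pid_continuous(s)
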