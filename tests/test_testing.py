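"""Permutation and adversarial (conservative) significance testing."""

import dataclasses

import numpy as np
import pytest

from triatoms.registry import MeasureSpec
from triatoms.sim_models import GroundTruthModel, NoiseFractions, strategy_to_fractions
from triatoms.testing import (
    ADVERSARIAL_SETS,
    CriticalValue,
    SearchConfig,
    TestConfig,
    TripletGenerator,
    adversarial_cv_red_syn,
    adversarial_cv_unique,
    adversarial_models,
    conservative_test,
    fraction_significant,
    permutation_critical_value,
    permute_target,
    upper_quantile,
)

TINY_SEARCH = SearchConfig(grid_steps=6, screen_reps=30, refine_reps=120)


def test_permute_target_preserves_sources_and_z_multiset(rng):
    gen = TripletGenerator("mUnq", "discrete", NoiseFractions(), 1000)
    s = gen.sample(3)
    p = permute_target(s, rng)
    np.testing.assert_array_equal(s.x, p.x)
    np.testing.assert_array_equal(s.y, p.y)
    assert sorted(s.z) == sorted(p.z)
    assert not np.array_equal(s.z, p.z)


def test_permute_target_breaks_source_target_relation(rng):
    gen = TripletGenerator("mUnq", "continuous", NoiseFractions(), 10_000)
    s = gen.sample(4)
    p = permute_target(s, rng)
    assert abs(np.corrcoef(p.x, p.z)[0, 1]) < 3 / np.sqrt(s.n)


def test_upper_quantile_order_statistic(rng):
    # rank ceil((1 - alpha)(m + 1)) of 10,000 uniforms sits near 0.99
    u = rng.random(10_000)
    assert upper_quantile(u, 0.01) == pytest.approx(0.99, abs=0.005)
    assert upper_quantile(np.full(100, 2.5), 0.01) == 2.5
    # small m caps at the maximum
    assert upper_quantile(np.arange(10.0), 0.01) == 9.0


def test_upper_quantile_monotone_in_alpha(rng):
    u = rng.random(2000)
    assert upper_quantile(u, 0.005) >= upper_quantile(u, 0.05)


def test_permutation_cv_is_deterministic_and_nonnegative():
    cfg = TestConfig(n_samples=400, n_null=600, n_test=10, seed=11)
    gen = TripletGenerator("mUnq", "discrete", NoiseFractions(0.1, 0.1, 0.1), 400)
    spec = MeasureSpec("pcorr", "unq_x")
    cv1 = permutation_critical_value(spec, gen, cfg)
    cv2 = permutation_critical_value(spec, gen, cfg)
    assert cv1.value == cv2.value
    assert cv1.value >= 0.0  # |PCorr| statistic
    assert cv1.provenance == "permutation"


def test_permutation_cv_fixed_dataset_mode():
    cfg = TestConfig(n_samples=400, n_null=600, n_test=10, seed=11)
    gen = TripletGenerator("mUnq", "discrete", NoiseFractions(0.1, 0.1, 0.1), 400)
    spec = MeasureSpec("pcorr", "unq_x")
    cv = permutation_critical_value(spec, gen, cfg, mode="fixed")
    assert 0.0 < cv.value < 1.0
    with pytest.raises(ValueError):
        permutation_critical_value(spec, gen, cfg, mode="bogus")


def test_small_null_warns():
    cfg = TestConfig(n_samples=200, n_null=100, n_test=10, seed=1)
    gen = TripletGenerator("mUnq", "discrete", NoiseFractions(), 200)
    with pytest.warns(UserWarning, match="unstable"):
        permutation_critical_value(MeasureSpec("pcorr", "unq_x"), gen, cfg)


def test_fraction_significant_true_positive_and_trivial_reject():
    cfg = TestConfig(n_samples=500, n_null=300, n_test=200, seed=13)
    gen = TripletGenerator("mUnq", "continuous", NoiseFractions(0, 0, 0.1), 500)
    spec = MeasureSpec("pcorr", "unq_x")
    cv = permutation_critical_value(spec, gen, cfg)
    summary = fraction_significant(spec, gen, cv, cfg)
    assert summary.fraction_significant > 0.95
    assert summary.above_chance

    # an unreachable critical value yields zero significance
    high = dataclasses.replace(cv, value=2.0)
    summary0 = fraction_significant(spec, gen, high, cfg)
    assert summary0.fraction_significant == 0.0
    assert not summary0.above_chance
    assert summary0.binomial_p == pytest.approx(1.0)


def test_conservative_test_is_strict_exceedance():
    cv = CriticalValue(0.5, "adjusted", MeasureSpec("vp", "red"))
    assert not conservative_test(0.5, cv)
    assert conservative_test(0.5000001, cv)
    with pytest.raises(ValueError):
        conservative_test(float("nan"), cv)


def test_cv_monotone_in_alpha_for_permutation_null():
    gen = TripletGenerator("mUnq", "discrete", NoiseFractions(0.2, 0.2, 0.2), 300)
    spec = MeasureSpec("pcorr", "unq_x")
    cvs = []
    for alpha in (0.1, 0.01):
        cfg = TestConfig(alpha=alpha, n_samples=300, n_null=500, n_test=10, seed=17)
        cvs.append(permutation_critical_value(spec, gen, cfg).value)
    assert cvs[1] >= cvs[0]


def test_adversarial_registry_structure():
    pcorr_atoms = {a for (m, a) in ADVERSARIAL_SETS if m == "pcorr"}
    assert pcorr_atoms == {"unq_x", "unq_y"}
    # mSum is adversarial only for VP redundancy/synergy
    for (measure, atom), models in ADVERSARIAL_SETS.items():
        if GroundTruthModel.mSum in models:
            assert measure == "vp" and atom in ("red", "syn")
    # a model never appears in the adversarial set of its own true atom
    assert GroundTruthModel.mRed not in ADVERSARIAL_SETS[("vp", "red")]
    assert GroundTruthModel.mXOR not in ADVERSARIAL_SETS[("mmi_discrete", "syn")]
    assert adversarial_models(MeasureSpec("broja", "syn")) == (
        GroundTruthModel.mRed,
        GroundTruthModel.mUnq,
    )


def test_adversarial_cv_unique_searches_the_diagonal():
    cfg = TestConfig(n_samples=600, n_null=50, n_test=50, seed=19)
    spec = MeasureSpec("pcorr", "unq_x")
    cv = adversarial_cv_unique(spec, "mRed", "discrete", cfg, TINY_SEARCH)
    assert cv.provenance == "adjusted"
    px, py, pz = cv.argmax_noise.as_tuple()
    assert px == py == pz
    # noise-induced bias: the adjusted CV clearly exceeds the zero-noise null
    gen0 = TripletGenerator("mRed", "discrete", NoiseFractions(), 600)
    cfg0 = dataclasses.replace(cfg, n_null=300)
    cv0 = permutation_critical_value(spec, gen0, cfg0)
    assert cv.value > cv0.value


def test_adversarial_cv_exceeds_permutation_cv_at_argmax():
    cfg = TestConfig(n_samples=600, n_null=300, n_test=10, seed=23)
    spec = MeasureSpec("pcorr", "unq_x")
    cv = adversarial_cv_unique(spec, "mRed", "discrete", cfg, TINY_SEARCH)
    wins = 0
    for seed in (1, 2, 3):
        gen = TripletGenerator("mRed", "discrete", cv.argmax_noise, 600)
        perm = permutation_critical_value(
            spec, gen, dataclasses.replace(cfg, seed=seed)
        )
        wins += cv.value >= perm.value
    assert wins >= 2


def test_adversarial_cv_red_syn_is_max_over_models_and_lines():
    cfg = TestConfig(n_samples=500, n_null=50, n_test=50, seed=29)
    spec = MeasureSpec("vp", "red")
    combined = adversarial_cv_red_syn(spec, None, "discrete", cfg, TINY_SEARCH)
    per_model = [
        adversarial_cv_red_syn(spec, (m,), "discrete", cfg, TINY_SEARCH)
        for m in adversarial_models(spec)
    ]
    assert combined.value == pytest.approx(max(c.value for c in per_model))
    assert combined.line in ("diagonal", "sources_only")
    with pytest.raises(ValueError):
        adversarial_cv_red_syn(spec, (), "discrete", cfg, TINY_SEARCH)


def test_continuous_search_floors_noise_fractions():
    cfg = TestConfig(n_samples=300, n_null=20, n_test=20, seed=31)
    spec = MeasureSpec("vp", "syn")
    search = SearchConfig(grid_steps=4, screen_reps=15, refine_reps=30)
    cv = adversarial_cv_red_syn(spec, ("mRed",), "continuous", cfg, search)
    assert min(cv.argmax_noise.as_tuple()[:2]) >= search.continuous_floor
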