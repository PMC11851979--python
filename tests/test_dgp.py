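"""Data-generating process: latent draws, Likertization, formulas,
coefficients, and seed determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mssr.conditions import Complexity, ConditionSpec, ConfigurationError, all_conditions
from mssr.dgp import (
    CoefficientSet,
    FORMULAS,
    draw_coefficients,
    evaluate_outcome,
    formula_for,
    generate_dataset,
    likertize,
    simulate_latent,
)

# ---------------------------------------------------------------------------
# Likertization
# ---------------------------------------------------------------------------


@given(st.floats(min_value=-50, max_value=50, allow_nan=False))
@settings(derandomize=True, max_examples=200)
def test_likertize_maps_reals_into_scale_and_is_idempotent(x):
    v = likertize(np.array([[x]]))[0, 0]
    assert 1 <= v <= 5
    assert likertize(np.array([[float(v)]]))[0, 0] == v


@pytest.mark.parametrize(
    "latent, expected",
    [(3.2, 4), (-0.7, 1), (6.3, 5), (3.0, 3), (0.999, 1), (4.0001, 5)],
)
def test_likertize_ceiling_then_clip(latent, expected):
    assert likertize(np.array([[latent]]))[0, 0] == expected


def test_likertize_is_monotone_nondecreasing():
    xs = np.sort(np.random.default_rng(0).uniform(-2, 8, size=500))
    coded = likertize(xs[None, :]).ravel()
    assert np.all(np.diff(coded) >= 0)


def test_likert_cell_frequencies_match_normal_tail_probabilities():
    """Cell probabilities are the N(3,1) interval masses with the tails
    absorbed at 1 and 5."""
    x = simulate_latent(100_000, 3, seed=99)
    coded = likertize(x)
    expected = np.diff(stats.norm.cdf([-np.inf, 1, 2, 3, 4, np.inf], loc=3))
    for v in range(1, 6):
        freq = np.mean(coded == v)
        assert freq == pytest.approx(expected[v - 1], abs=0.01)


# ---------------------------------------------------------------------------
# latent predictors
# ---------------------------------------------------------------------------


def test_latent_moments_at_large_n():
    x = simulate_latent(100_000, 5, seed=7)
    assert x.shape == (100_000, 5)
    assert np.allclose(x.mean(axis=0), 3.0, atol=0.02)
    assert np.allclose(x.std(axis=0, ddof=1), 1.0, atol=0.02)


def test_latent_shape_determinism_and_seed_sensitivity():
    a = simulate_latent(5, 3, seed=11)
    assert a.shape == (5, 3)
    assert np.array_equal(a, simulate_latent(5, 3, seed=11))
    assert not np.array_equal(a, simulate_latent(5, 3, seed=12))


def test_latent_rejects_invalid_n_iv():
    with pytest.raises(ConfigurationError):
        simulate_latent(10, 4, seed=0)


# ---------------------------------------------------------------------------
# coefficients
# ---------------------------------------------------------------------------


def test_coefficient_ranges_and_gap():
    """Small-level draws stay in [0.1, 0.3], large-level in [0.5, 1];
    nothing falls in the open gap (0.3, 0.5)."""
    for cond in all_conditions():
        cs = draw_coefficients(cond, seed=3)
        lo, hi = (0.1, 0.3) if cond.linear_level == "small" else (0.5, 1.0)
        assert all(lo <= c <= hi for c in cs.cof)
        lo, hi = (0.1, 0.3) if cond.nonlinear_level == "small" else (0.5, 1.0)
        assert all(lo <= c <= hi for c in cs.conf)
        assert not any(0.3 < c < 0.5 for c in cs.cof + cs.conf)
        assert cs.coferr == cond.error_coef


def test_coefficient_lengths_match_formula_term_counts():
    expected = {
        (Complexity.SIMPLE, 3): (3, 2),
        (Complexity.MEDIUM, 3): (3, 4),
        (Complexity.HIGH, 3): (3, 5),
        (Complexity.SIMPLE, 5): (3, 2),
        (Complexity.MEDIUM, 5): (3, 4),
        (Complexity.HIGH, 5): (3, 4),   # conf1 multiplies both interactions
        (Complexity.SIMPLE, 10): (6, 2),
        (Complexity.MEDIUM, 10): (6, 4),
        (Complexity.HIGH, 10): (6, 5),  # includes the literal conf5*x9 term
    }
    for key, (n_cof, n_conf) in expected.items():
        assert (FORMULAS[key].n_cof, FORMULAS[key].n_conf) == (n_cof, n_conf)


def test_coefficient_determinism(cond_medium3):
    assert draw_coefficients(cond_medium3, 5) == draw_coefficients(cond_medium3, 5)
    assert draw_coefficients(cond_medium3, 5) != draw_coefficients(cond_medium3, 6)


# ---------------------------------------------------------------------------
# outcome evaluation
# ---------------------------------------------------------------------------


def test_outcome_hand_computed_values(cond_medium3, eq10_noiseless):
    """The printed medium-complexity 3-IV coefficient set evaluated by hand
    at x=(1,1,1) and x=(3,3,3)."""
    y1 = evaluate_outcome(np.ones((1, 3)), cond_medium3, eq10_noiseless)
    assert y1[0] == pytest.approx(3.572, abs=1e-9)
    y3 = evaluate_outcome(np.full((1, 3), 3.0), cond_medium3, eq10_noiseless)
    assert y3[0] == pytest.approx(27.948, abs=1e-9)


def test_outcome_degenerate_all_zero_coefficients(cond_medium3):
    """With every structural coefficient zero, Y is pure coferr-scaled
    standard-normal noise."""
    cs = CoefficientSet(cof=(0.0,) * 3, conf=(0.0,) * 4, coferr=4.0)
    x = simulate_latent(50_000, 3, seed=21)
    y = evaluate_outcome(x, cond_medium3, cs, noise_seed=22)
    assert y.var() == pytest.approx(16.0, rel=0.05)
    assert y.mean() == pytest.approx(0.0, abs=0.1)


def test_outcome_linear_in_each_coefficient(cond_medium3, eq10_noiseless):
    """Finite-difference check: Y is linear in every coefficient holding
    the others fixed."""
    x = simulate_latent(50, 3, seed=33)
    base = evaluate_outcome(x, cond_medium3, eq10_noiseless)
    for slot in range(4):
        conf = list(eq10_noiseless.conf)
        conf[slot] += 1.0
        bumped = CoefficientSet(cof=eq10_noiseless.cof, conf=tuple(conf), coferr=0.0)
        delta = evaluate_outcome(x, cond_medium3, bumped) - base
        conf[slot] += 1.0
        bumped2 = CoefficientSet(cof=eq10_noiseless.cof, conf=tuple(conf), coferr=0.0)
        delta2 = evaluate_outcome(x, cond_medium3, bumped2) - base
        assert np.allclose(delta2, 2 * delta)


def test_outcome_rejects_mismatched_coefficients(cond_medium3):
    bad = CoefficientSet(cof=(0.1, 0.2), conf=(0.5,), coferr=1.0)
    with pytest.raises(ConfigurationError):
        evaluate_outcome(np.ones((2, 3)), cond_medium3, bad)


def test_high_complexity_10iv_has_literal_x9_term():
    """The last nonlinear term of the high-complexity 10-IV formula is the
    plain conf5*x9, as published."""
    cond = ConditionSpec(complexity=3, n_iv=10, linear_level="small",
                         nonlinear_level="small", error_coef=1)
    f = formula_for(cond)
    term, ci = f.nonlinear_terms[-1]
    assert term == ("main", 9)
    assert ci == 4
    x = np.ones((1, 10))
    cs0 = CoefficientSet(cof=(0,) * 6, conf=(0, 0, 0, 0, 1.0), coferr=0.0)
    assert evaluate_outcome(x, cond, cs0)[0] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# dataset composition
# ---------------------------------------------------------------------------


def test_dataset_composition_and_determinism(cond_medium3, eq10):
    ds = generate_dataset(cond_medium3, 1000, eq10, seed=9)
    assert ds.X.shape == (1000, 3)
    assert ds.Y.shape == (1000,)
    assert set(np.unique(ds.X)) <= {1, 2, 3, 4, 5}
    assert np.array_equal(ds.X, likertize(ds.latent))
    again = generate_dataset(cond_medium3, 1000, eq10, seed=9)
    assert np.array_equal(ds.X, again.X) and np.array_equal(ds.Y, again.Y)


def test_outcome_uses_latent_not_likert_values(cond_medium3, eq10_noiseless):
    ds = generate_dataset(cond_medium3, 200, eq10_noiseless, seed=14)
    from_latent = evaluate_outcome(ds.latent, cond_medium3, eq10_noiseless)
    from_likert = evaluate_outcome(ds.X.astype(float), cond_medium3, eq10_noiseless)
    assert np.allclose(ds.Y, from_latent)
    assert not np.allclose(ds.Y, from_likert)


def test_zero_nonlinear_noiseless_outcome_is_linear_in_latent(linear_condition):
    """With conf=0 and coferr→0 the outcome correlates ~1 with the linear
    predictor of the latent scores."""
    cs = CoefficientSet(cof=(0.9, 0.7, 0.8), conf=(0.0, 0.0), coferr=0.001)
    ds = generate_dataset(linear_condition, 10_000, cs, seed=15)
    lin_pred = ds.latent @ np.array(cs.cof)
    r = np.corrcoef(ds.Y, lin_pred)[0, 1]
    assert r > 0.9999
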