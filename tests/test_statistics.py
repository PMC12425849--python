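"""Per-participant statistics against independent oracles, and the
directional sign-flipping filter test."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from nondirtest import (
    auroc2_difference,
    cohen_d,
    directional_sign_flip_test,
    dprime,
    get_statistic,
    interaction_contrast,
    mean_difference,
    phi,
    phi_counts,
    type2_auroc,
)
from nondirtest.data import ParticipantData

from conftest import make_part


def _swap(part):
    return part.with_condition(1 - part.cond)


class TestMeanDifference:
    def test_forced_means(self):
        part = make_part([1, 2, 3], [3, 4, 5])
        assert mean_difference(part) == pytest.approx(2.0)
        assert mean_difference(_swap(part)) == pytest.approx(-2.0)

    def test_identical_distributions_zero(self):
        part = make_part([1, 2, 3], [1, 2, 3])
        assert mean_difference(part) == 0.0

    def test_empty_cell_errors(self):
        part = make_part([1, 2], [3])
        part = part.subset(np.array([0, 1]))
        with pytest.raises(ValueError, match="empty condition cell"):
            mean_difference(part)


class TestCohenD:
    def test_hand_calculation(self):
        # cells [0,0,1,1] vs [1,1,2,2]: mean diff 1, per-cell var 1/3,
        # pooled sd sqrt(1/3)  ->  d = sqrt(3)
        part = make_part([0, 0, 1, 1], [1, 1, 2, 2])
        assert cohen_d(part) == pytest.approx(np.sqrt(3.0))

    def test_equal_means_zero(self):
        part = make_part([1, 2, 3], [3, 1, 2])
        assert cohen_d(part) == pytest.approx(0.0)

    def test_scale_and_shift_invariance(self):
        rng = np.random.default_rng(3)
        y0, y1 = rng.normal(size=10), rng.normal(1, 1, size=10)
        d = cohen_d(make_part(y0, y1))
        assert cohen_d(make_part(10 * y0, 10 * y1)) == pytest.approx(d)
        assert cohen_d(make_part(y0 + 7, y1 + 7)) == pytest.approx(d)

    def test_zero_pooled_sd_errors(self):
        with pytest.raises(ValueError, match="zero pooled SD"):
            cohen_d(make_part([1, 1, 1], [2, 2, 2]))


class TestDprime:
    def test_equal_rates_zero(self):
        part = make_part([1, 0] * 5, [1, 0] * 5)
        assert dprime(part) == pytest.approx(0.0)

    def test_closed_form(self):
        part = make_part([1, 1, 0, 0, 0, 0, 0, 0, 0, 0], [1] * 9 + [0])
        expected = sps.norm.ppf(0.9) - sps.norm.ppf(0.2)
        assert dprime(part) == pytest.approx(expected)

    def test_extreme_rate_correction(self):
        part = make_part([0] * 10, [1] * 10)
        expected = sps.norm.ppf(0.95) - sps.norm.ppf(0.05)
        assert dprime(part) == pytest.approx(expected)

    def test_requires_binary(self):
        with pytest.raises(ValueError, match="binary"):
            dprime(make_part([0.2, 0.4], [1, 0]))


class TestPhi:
    def test_independence_zero(self):
        assert phi_counts(10, 10, 10, 10) == pytest.approx(0.0)

    def test_perfect_association(self):
        assert phi_counts(10, 0, 0, 10) == pytest.approx(1.0)

    def test_arithmetic_oracle(self):
        a, b, c, d = 8, 2, 3, 7
        expected = (a * d - b * c) / np.sqrt(
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        assert phi_counts(a, b, c, d) == pytest.approx(expected)
        part = make_part([1] * c + [0] * d, [1] * a + [0] * b)
        assert phi(part) == pytest.approx(expected)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError, match="zero margin"):
            phi_counts(5, 5, 0, 0)


def _auroc_pairwise_oracle(correct, conf):
    """Exhaustive pairwise comparisons with half credit for ties."""
    correct = np.asarray(correct, bool)
    conf = np.asarray(conf, float)
    pos, neg = conf[correct], conf[~correct]
    total = wins = 0.0
    for p in pos:
        for n in neg:
            total += 1
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / total


class TestType2Auroc:
    def test_confidence_independent_of_accuracy(self):
        assert type2_auroc([1, 1, 0, 0], [3, 3, 3, 3]) == pytest.approx(0.5)

    def test_perfect_metacognition(self):
        assert type2_auroc([1, 1, 1, 0, 0], [4, 4, 3, 2, 1]) == pytest.approx(1.0)

    def test_tied_levels_match_pairwise_oracle(self):
        correct = [1, 1, 0, 1, 0, 0]
        conf = [3, 2, 2, 1, 1, 1]
        assert type2_auroc(correct, conf) == pytest.approx(
            _auroc_pairwise_oracle(correct, conf)
        )

    @settings(deadline=None, max_examples=60)
    @given(st.data())
    def test_property_matches_oracle_on_random_instances(self, data):
        n = data.draw(st.integers(6, 12))
        correct = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda c: 0 < sum(c) < len(c)
            )
        )
        conf = data.draw(st.lists(st.integers(1, 4), min_size=n, max_size=n))
        assert type2_auroc(correct, conf) == pytest.approx(
            _auroc_pairwise_oracle(correct, conf)
        )

    def test_degenerate_cell_raises_undefined(self):
        from nondirtest import UndefinedStatisticError

        with pytest.raises(UndefinedStatisticError):
            type2_auroc([1, 1, 1], [1, 2, 3])

    def test_auroc2_difference_conditioning_swap_flips_sign(self):
        part = make_part(
            [1, 1, 0, 0, 1, 0], [1, 0, 1, 0, 0, 1],
            accuracy=[1, 1, 0, 0, 1, 0, 1, 0, 1, 0, 0, 1],
            confidence=[3, 2, 1, 2, 3, 1, 2, 2, 3, 1, 2, 3],
        )
        assert auroc2_difference(_swap(part)) == pytest.approx(
            -auroc2_difference(part)
        )


def _two_factor_part(cell_means, n=3, noise=None):
    rows_y, rows_c, rows_c2 = [], [], []
    rng = np.random.default_rng(0)
    for (a, b), mu in cell_means.items():
        y = np.full(n, float(mu))
        if noise:
            y = y + rng.normal(0, noise, n)
        rows_y.append(y)
        rows_c.append(np.full(n, a))
        rows_c2.append(np.full(n, b))
    return ParticipantData(
        pid="p",
        y=np.concatenate(rows_y),
        cond=np.concatenate(rows_c).astype(int),
        cond2=np.concatenate(rows_c2).astype(int),
    )


class TestInteractionContrast:
    def test_additive_means_no_interaction(self):
        part = _two_factor_part({(0, 0): 1, (0, 1): 3, (1, 0): 5, (1, 1): 7})
        assert interaction_contrast(part) == pytest.approx(0.0)

    def test_single_loaded_cell(self):
        part = _two_factor_part({(0, 0): 0, (0, 1): 0, (1, 0): 0, (1, 1): 10})
        assert interaction_contrast(part) == pytest.approx(10.0)

    def test_random_cells_match_cell_mean_arithmetic(self):
        rng = np.random.default_rng(42)
        mus = {k: rng.normal() for k in product((0, 1), (0, 1))}
        part = _two_factor_part(mus, n=4, noise=1.0)
        means = {
            k: part.y[(part.cond == k[0]) & (part.cond2 == k[1])].mean()
            for k in mus
        }
        expected = (means[1, 1] - means[1, 0]) - (means[0, 1] - means[0, 0])
        assert interaction_contrast(part) == pytest.approx(expected)


@pytest.mark.parametrize("name", ["mean_diff", "cohen_d", "dprime_diff", "phi"])
def test_statistics_are_antisymmetric_under_convention_swap(name):
    rng = np.random.default_rng(8)
    if name in ("dprime_diff", "phi"):
        y0 = rng.integers(0, 2, 12).astype(float)
        y1 = rng.integers(0, 2, 12).astype(float)
        y0[:2], y1[:2] = [0, 1], [0, 1]  # both values present in both cells
    else:
        y0, y1 = rng.normal(size=8), rng.normal(size=8)
    part = make_part(y0, y1)
    stat = get_statistic(name)
    assert stat(_swap(part)) == pytest.approx(-stat(part))


class TestDirectionalSignFlip:
    def test_all_zero_effects(self):
        assert directional_sign_flip_test([0, 0, 0, 0]) == 1.0

    def test_exhaustive_three_participant_oracle(self):
        effects = np.array([2.0, -1.0, 0.5])
        observed = abs(effects.mean())
        null = [
            abs(np.mean([s0 * 2.0, s1 * -1.0, s2 * 0.5]))
            for s0, s1, s2 in product((-1, 1), repeat=3)
        ]
        expected = np.mean([v >= observed - 1e-12 for v in null])
        assert directional_sign_flip_test(effects) == pytest.approx(expected)

    def test_strong_same_signed_effects_significant(self):
        effects = np.full(15, 10.0) + np.random.default_rng(1).normal(0, 1, 15)
        assert directional_sign_flip_test(effects) < 0.01

    def test_monte_carlo_path_close_to_exhaustive(self):
        effects = np.random.default_rng(2).normal(0.3, 1.0, 12)
        exact = directional_sign_flip_test(effects)
        mc = directional_sign_flip_test(
            effects, n_flips=20_000, seed=4, exhaustive_limit=5
        )
        assert mc == pytest.approx(exact, abs=0.02)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            directional_sign_flip_test([1.0])
        with pytest.raises(ValueError):
            directional_sign_flip_test([1.0, 2.0], n_flips=0)
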