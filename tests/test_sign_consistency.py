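"""Sign Consistency test: split-half scores against exhaustive oracles, sign
invariance, null behaviour and reproducibility."""

from itertools import combinations

import numpy as np
import pytest

from nondirtest import (
    ScenarioParams,
    SignConsistency,
    participant_sign_consistency,
    simulate_scenario,
)

from conftest import make_part, make_table


def _exhaustive_split_sc(y0, y1):
    """Oracle: enumerate every stratified split-half (first half receives
    floor(m/2) of each cell) and return the exact expected agreement."""
    y0, y1 = np.asarray(y0, float), np.asarray(y1, float)
    k0, k1 = y0.size // 2, y1.size // 2
    agree = total = 0
    for h0 in combinations(range(y0.size), k0):
        rest0 = [i for i in range(y0.size) if i not in h0]
        for h1 in combinations(range(y1.size), k1):
            rest1 = [i for i in range(y1.size) if i not in h1]
            d1 = y1[list(h1)].mean() - y0[list(h0)].mean()
            d2 = y1[rest1].mean() - y0[rest0].mean()
            total += 1
            agree += int(np.sign(d1) == np.sign(d2) != 0)
    return agree / total


class TestParticipantScore:
    def test_widely_separated_conditions_fully_consistent(self):
        part = make_part([1, 2, 3, 2, 1, 3], [101, 102, 103, 102, 101, 103])
        assert participant_sign_consistency(part, seed=0) == 1.0

    def test_exhaustive_oracle_on_label_copies(self):
        # conditions identical value-for-value -> low consistency,
        # matching the exact enumeration over all 4+4 stratified splits
        y = [1.0, 2.0, 3.0, 10.0]
        oracle = _exhaustive_split_sc(y, y)
        mc = participant_sign_consistency(
            make_part(y, y), n_splits=4000, seed=1
        )
        tol = 4 * np.sqrt(max(oracle * (1 - oracle), 0.005) / 4000)
        assert abs(mc - oracle) <= tol

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exhaustive_oracle_random_small_participants(self, seed):
        rng = np.random.default_rng(seed)
        y0 = rng.normal(0, 1, 5)
        y1 = rng.normal(0.5, 1, 5)
        oracle = _exhaustive_split_sc(y0, y1)
        mc = participant_sign_consistency(
            make_part(y0, y1), n_splits=5000, seed=seed
        )
        assert abs(mc - oracle) < 4 * np.sqrt(
            max(oracle * (1 - oracle), 0.01) / 5000
        )

    def test_generic_path_agrees_with_fast_path(self):
        rng = np.random.default_rng(9)
        part = make_part(rng.normal(size=8), rng.normal(0.8, 1, 8))
        from nondirtest.sign_consistency import (
            _sc_generic,
            _sc_mean_diff,
            split_schedule,
        )
        from nondirtest.statistics import mean_difference

        schedule = split_schedule([8, 8], 300, np.random.default_rng(0))
        fast = _sc_mean_diff(part.y[part.cond == 0], part.y[part.cond == 1],
                             schedule)
        slow = _sc_generic(part, mean_difference, schedule)
        assert fast == pytest.approx(slow)

    def test_sign_convention_invariance(self):
        # agreement is sign-free: identical splits give identical SC after
        # swapping which level counts as positive
        from nondirtest import split_schedule

        rng = np.random.default_rng(4)
        part = make_part(rng.normal(size=6), rng.normal(1, 1, 6))
        h0, h1 = split_schedule([6, 6], 200, np.random.default_rng(5))
        sc = participant_sign_consistency(part, schedule=[h0, h1])
        swapped = part.with_condition(1 - part.cond)
        # after the swap the old positive cell is stratum 0
        assert participant_sign_consistency(
            swapped, schedule=[h1, h0]
        ) == pytest.approx(sc)

    def test_too_few_trials_errors_with_participant(self):
        with pytest.raises(ValueError, match="p1"):
            participant_sign_consistency(make_part([1.0], [2.0, 3.0]), seed=0)

    def test_monotone_in_standardised_effect(self):
        # larger |e|/sigma_w -> higher expected consistency
        rng = np.random.default_rng(11)
        means = []
        for effect in (0.0, 0.5, 1.5):
            scs = [
                participant_sign_consistency(
                    make_part(rng.normal(0, 1, 20), rng.normal(effect, 1, 20)),
                    n_splits=200,
                    seed=s,
                )
                for s in range(40)
            ]
            means.append(np.mean(scs))
        assert means[0] < means[1] < means[2]


class TestModel:
    def test_group_stat_is_mean_of_scores(self, nd_dataset):
        res = SignConsistency(nd_dataset.table).fit(
            n_permutations=30, n_null=500, seed=3
        )
        assert res.group_stat == pytest.approx(float(res.scores.mean()))
        assert res.n_participants == 15
        assert "Sign Consistency" in res.summary()

    def test_seed_determinism(self, nd_dataset):
        a = SignConsistency(nd_dataset.table).fit(
            n_permutations=20, n_null=300, seed=9
        )
        b = SignConsistency(nd_dataset.table).fit(
            n_permutations=20, n_null=300, seed=9
        )
        assert a.pvalue == b.pvalue
        assert np.array_equal(a.null.samples, b.null.samples)
        assert a.scores.equals(b.scores)

    def test_null_mean_sc_near_half(self):
        # E[SC] = 0.5 under the global null with continuous outcomes
        total, count = 0.0, 0
        for s in range(200):
            sim = simulate_scenario(
                ScenarioParams.global_null(n_participants=4, n_trials=10),
                seed=1000 + s,
            )
            for part in sim.table.iter_participants():
                total += participant_sign_consistency(
                    part, n_splits=60, seed=s
                )
                count += 1
        assert abs(total / count - 0.5) < 0.02

    def test_needs_two_participants(self, mk_table):
        table = mk_table({"p1": ([1, 2, 3], [4, 5, 6])})
        with pytest.raises(ValueError, match="2 participants"):
            SignConsistency(table)

    def test_not_anticonservative_under_global_null(self):
        # iid outcomes independent of labels: p-values must not pile up
        # near zero (full calibration is exercised at scale elsewhere)
        rng = np.random.default_rng(21)
        pvals = []
        for rep in range(40):
            cells = {f"p{i}": (rng.normal(size=8), rng.normal(size=8))
                     for i in range(5)}
            table = make_table(cells)
            res = SignConsistency(table, n_splits=100).fit(
                n_permutations=50, n_null=400, seed=rep
            )
            pvals.append(res.pvalue)
        # P(X >= 7 | 40, .05) < 0.001 under correct calibration
        assert np.sum(np.asarray(pvals) < 0.05) <= 6
        assert 0.1 < np.median(pvals) < 0.99

    def test_label_copy_table_is_conservative(self):
        # conditions that are value-for-value copies are a maximally
        # balanced label assignment: shuffling only increases apparent
        # consistency, so the test should never fire
        rng = np.random.default_rng(22)
        cells = {}
        for i in range(5):
            y = rng.normal(size=8)
            cells[f"p{i}"] = (y, rng.permutation(y))
        res = SignConsistency(make_table(cells), n_splits=100).fit(
            n_permutations=50, n_null=400, seed=0
        )
        assert res.pvalue > 0.2
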