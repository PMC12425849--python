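"""The Sign Consistency test.

A within-participant effect is credible if it shows the same sign in
independent halves of that participant's data.  For each participant we
repeatedly (default 500 times) split their trials into two random halves,
stratified by condition cell, compute the chosen signed statistic on each
half, and record whether the two halves agree in sign.  The proportion of
agreeing splits is the participant's sign-consistency score SC in [0, 1];
under no effect and a continuous outcome the halves are independent
coin-flips and E[SC] = 0.5.

The group mean SC is tested (one-sided, greater) against a two-stage
permutation null: condition labels are shuffled within participants
(default 100 permutations each), SC is recomputed on each shuffled copy
with the *same* split schedule, and 10,000 group-level null samples are
drawn by averaging one bank value per participant.

A split in which either half's statistic is exactly zero counts as
inconsistent (zero carries no sign).  With continuous outcomes this is a
measure-zero event; with binary outcomes it is not, which makes the score
conservative there.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .base import TrialModel, NonDirectionalResults
from .data import ParticipantData
from .permutation import as_seed_sequence, build_null, p_value, permute_labels
from .statistics import get_statistic, UndefinedStatisticError

__all__ = ["SignConsistency", "participant_sign_consistency", "split_schedule"]

logger = logging.getLogger(__name__)


def split_schedule(strata_sizes, n_splits: int, rng) -> list[np.ndarray]:
    """Random stratified split-half schedule.

    For each stratum (condition cell) of size m, returns a boolean matrix
    (n_splits, m): True marks membership of the first half, which receives
    floor(m/2) trials; the second half receives the rest (ceil(m/2) when m
    is odd).
    """
    schedule = []
    for m in strata_sizes:
        if m < 2:
            raise ValueError("each condition cell needs >=2 trials to split")
        k = m // 2
        order = np.argsort(rng.random((n_splits, m)), axis=1)
        mask = np.zeros((n_splits, m), dtype=bool)
        np.put_along_axis(mask, order[:, :k], True, axis=1)
        schedule.append(mask)
    return schedule


def _agreement(d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    # same nonzero sign in both halves; a zero in either half is inconsistent
    return (np.sign(d1) * np.sign(d2)) > 0


def _sc_mean_diff(y0, y1, schedule) -> float:
    """Vectorised SC over a precomputed schedule, mean-difference statistic."""
    h0, h1 = schedule
    k0, k1 = h0.shape[1] // 2, h1.shape[1] // 2
    d_first = (h1 @ y1) / k1 - (h0 @ y0) / k0
    d_second = ((~h1) @ y1) / (h1.shape[1] - k1) - ((~h0) @ y0) / (h0.shape[1] - k0)
    return float(np.mean(_agreement(d_first, d_second)))


def _sc_mean_diff_bank(part: ParticipantData, M: int, rng, schedule) -> np.ndarray:
    """SC of M label-shuffled copies at once (mean-difference statistic).

    A label shuffle preserving cell sizes is equivalent to permuting the
    pooled outcomes and reading the first m0 as cell 0: each permutation
    row here is one shuffled copy, pushed through the same split schedule.
    """
    y0 = part.y[part.cond == 0]
    y1 = part.y[part.cond == 1]
    m0 = y0.size
    pooled = np.concatenate([y0, y1])
    perm = rng.permuted(
        np.tile(np.arange(pooled.size), (M, 1)), axis=1
    )
    v = pooled[perm]
    c0, c1 = v[:, :m0], v[:, m0:]
    h0, h1 = schedule
    k0, k1 = h0.shape[1] // 2, h1.shape[1] // 2
    d_first = (c1 @ h1.T) / k1 - (c0 @ h0.T) / k0
    d_second = (c1 @ (~h1).T) / (h1.shape[1] - k1) - (c0 @ (~h0).T) / (h0.shape[1] - k0)
    return np.mean(_agreement(d_first, d_second), axis=1)


def _sc_generic(part: ParticipantData, stat_fn, schedule) -> float:
    """SC by explicit looping over splits — works for any statistic."""
    strata = part.strata()
    n_splits = schedule[0].shape[0]
    agree = np.empty(n_splits, dtype=bool)
    for s in range(n_splits):
        first, second = [], []
        for idx, mask in zip(strata, schedule):
            first.append(idx[mask[s]])
            second.append(idx[~mask[s]])
        v1 = stat_fn(part.subset(np.concatenate(first)))
        v2 = stat_fn(part.subset(np.concatenate(second)))
        agree[s] = np.sign(v1) == np.sign(v2) != 0
    return float(np.mean(agree))


def participant_sign_consistency(
    part: ParticipantData,
    stat_fn="mean_diff",
    n_splits: int = 500,
    seed=None,
    schedule=None,
) -> float:
    """Sign-consistency score of one participant.

    Proportion of ``n_splits`` random stratified split-halves in which the
    statistic has the same nonzero sign in both halves.  A precomputed
    ``schedule`` (from :func:`split_schedule`) may be supplied; otherwise
    one is drawn from ``seed``.
    """
    name = stat_fn if isinstance(stat_fn, str) else None
    stat = get_statistic(stat_fn)
    sizes = [idx.size for idx in part.strata()]
    if min(sizes) < 2:
        raise ValueError(
            f"participant {part.pid!r}: every condition cell needs >=2 trials "
            "for split-half consistency"
        )
    if schedule is None:
        schedule = split_schedule(sizes, n_splits, np.random.default_rng(seed))
    if name == "mean_diff" and part.cond2 is None:
        return _sc_mean_diff(part.y[part.cond == 0], part.y[part.cond == 1], schedule)
    return _sc_generic(part, stat, schedule)


class SignConsistency(TrialModel):
    """Sign Consistency test model.

    Parameters
    ----------
    data : TrialTable
        Validated trial table (apply exclusions first; see
        :func:`nondirtest.apply_exclusions`).
    statistic : str or callable, default "mean_diff"
        Signed per-participant statistic whose split-half sign agreement is
        scored.
    n_splits : int, default 500
        Random stratified split-halves per participant.
    """

    def __init__(self, data, statistic="mean_diff", n_splits: int = 500):
        super().__init__(data)
        if len(self.parts) < 2:
            raise ValueError("sign-consistency test needs >=2 participants")
        self.statistic = statistic
        self.stat_name = statistic if isinstance(statistic, str) else getattr(
            statistic, "__name__", "custom"
        )
        self.n_splits = int(n_splits)
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")

    def fit(
        self,
        n_permutations: int = 100,
        n_null: int = 10_000,
        seed=None,
    ) -> NonDirectionalResults:
        """Run the test.

        ``n_permutations`` is the per-participant permutation bank size M,
        ``n_null`` the number B of group-level null samples.  The same
        seeded split schedule is reused for the observed and every permuted
        copy of each participant's data, so identical seeds give identical
        results bit-for-bit.
        """
        master = as_seed_sequence(seed)
        ss_sched, ss_null = master.spawn(2)
        sched_rngs = {}
        # schedules keyed by a stable sort of ids (row-order independent)
        pids = [p.pid for p in self.parts]
        children = ss_sched.spawn(len(pids))
        for rank, pid in enumerate(sorted(pids, key=str)):
            sched_rngs[pid] = np.random.default_rng(children[rank])

        stat = get_statistic(self.statistic)
        fast = self.stat_name == "mean_diff" and self.data.levels2 is None
        schedules, scores, dropped = {}, {}, {}
        for part in self.parts:
            sizes = [idx.size for idx in part.strata()]
            if min(sizes) < 2:
                raise ValueError(
                    f"participant {part.pid!r}: every condition cell needs "
                    ">=2 trials for split-half consistency"
                )
            schedule = split_schedule(sizes, self.n_splits, sched_rngs[part.pid])
            schedules[part.pid] = schedule
            try:
                scores[part.pid] = participant_sign_consistency(
                    part, self.statistic, self.n_splits, schedule=schedule
                )
            except UndefinedStatisticError as err:
                dropped[part.pid] = str(err)
                logger.warning("dropping participant %r: %s", part.pid, err)
        kept = [p for p in self.parts if p.pid in scores]
        if len(kept) < 2:
            raise ValueError("fewer than 2 participants with a defined score")

        if fast:
            def bank_fn(part, M, rng):
                return _sc_mean_diff_bank(part, M, rng, schedules[part.pid])
        else:
            def bank_fn(part, M, rng):
                out = np.empty(M)
                for m in range(M):
                    out[m] = _sc_generic(
                        permute_labels(part, rng), stat, schedules[part.pid]
                    )
                return out

        null = build_null(kept, None, M=n_permutations, B=n_null,
                          seed=ss_null, bank_fn=bank_fn)
        scores = pd.Series(scores, name="sign_consistency")
        group = float(scores.mean())
        p = p_value(group, null, direction="greater")
        return NonDirectionalResults(
            method="Sign Consistency Test",
            statistic=self.stat_name,
            scores=scores,
            group_stat=group,
            null=null,
            pvalue=p,
            params={"n_splits": self.n_splits, "seed": seed},
            dropped=dropped,
        )
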