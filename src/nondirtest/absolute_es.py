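"""The Absolute Effect Size test.

Complements sign consistency: a non-directional effect also shows up as
within-participant standardised effect sizes whose *magnitude* exceeds what
label noise alone produces.  Each participant contributes the absolute
value of a standardised signed statistic — Cohen's d for continuous
outcomes, a d' difference for binary accuracy, phi for binary response
categories — and the group mean of |ES| is compared (one-sided, greater)
against the same two-stage label-permutation null used by the
sign-consistency test, with |ES| recomputed on every shuffled copy.

Under the global null with N_t trials per condition, each participant's d
is approximately N(0, 2/N_t), so the group mean |d| concentrates around
the folded-normal mean sqrt(2/N_t) * sqrt(2/pi).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .base import TrialModel, NonDirectionalResults
from .data import ParticipantData
from .permutation import build_null, p_value, permuted_stat_bank
from .statistics import get_statistic, UndefinedStatisticError

__all__ = ["AbsoluteEffectSize", "participant_abs_effect"]

logger = logging.getLogger(__name__)


def participant_abs_effect(part: ParticipantData, stat_fn="cohen_d") -> float:
    """|statistic| of one participant's trials."""
    return abs(get_statistic(stat_fn)(part))


def _abs_cohen_d_bank(part: ParticipantData, M: int, rng) -> np.ndarray:
    """|d| of M label-shuffled copies at once, via per-row moments."""
    y0 = part.y[part.cond == 0]
    y1 = part.y[part.cond == 1]
    m0, m1 = y0.size, y1.size
    pooled = np.concatenate([y0, y1])
    perm = rng.permuted(np.tile(np.arange(pooled.size), (M, 1)), axis=1)
    v = pooled[perm]
    c0, c1 = v[:, :m0], v[:, m0:]
    mu0, mu1 = c0.mean(axis=1), c1.mean(axis=1)
    ss0 = ((c0 - mu0[:, None]) ** 2).sum(axis=1)
    ss1 = ((c1 - mu1[:, None]) ** 2).sum(axis=1)
    sp = np.sqrt((ss0 + ss1) / (m0 + m1 - 2))
    return np.abs(mu1 - mu0) / sp


def _abs_mean_diff_bank(part: ParticipantData, M: int, rng) -> np.ndarray:
    y0 = part.y[part.cond == 0]
    y1 = part.y[part.cond == 1]
    m0 = y0.size
    pooled = np.concatenate([y0, y1])
    perm = rng.permuted(np.tile(np.arange(pooled.size), (M, 1)), axis=1)
    v = pooled[perm]
    return np.abs(v[:, m0:].mean(axis=1) - v[:, :m0].mean(axis=1))


class AbsoluteEffectSize(TrialModel):
    """Absolute Effect Size test model.

    Parameters
    ----------
    data : TrialTable
        Validated trial table (apply exclusions first).
    statistic : str or callable, default "cohen_d"
        Signed statistic whose absolute value is tested.  Use "dprime_diff"
        for binary accuracy outcomes and "phi" for binary response
        categories.
    """

    def __init__(self, data, statistic="cohen_d"):
        super().__init__(data)
        if len(self.parts) < 2:
            raise ValueError("absolute effect size test needs >=2 participants")
        self.statistic = statistic
        self.stat_name = statistic if isinstance(statistic, str) else getattr(
            statistic, "__name__", "custom"
        )

    def fit(
        self,
        n_permutations: int = 100,
        n_null: int = 10_000,
        seed=None,
    ) -> NonDirectionalResults:
        """Run the test with bank size M=``n_permutations`` and
        B=``n_null`` group null samples."""
        stat = get_statistic(self.statistic)
        scores, dropped = {}, {}
        for part in self.parts:
            try:
                scores[part.pid] = abs(stat(part))
            except UndefinedStatisticError as err:
                dropped[part.pid] = str(err)
                logger.warning("dropping participant %r: %s", part.pid, err)
        kept = [p for p in self.parts if p.pid in scores]
        if len(kept) < 2:
            raise ValueError("fewer than 2 participants with a defined score")

        two_factor = self.data.levels2 is not None
        if self.stat_name == "cohen_d" and not two_factor:
            bank_fn = _abs_cohen_d_bank
        elif self.stat_name == "mean_diff" and not two_factor:
            bank_fn = _abs_mean_diff_bank
        else:
            def bank_fn(part, M, rng):
                return permuted_stat_bank(part, lambda q: abs(stat(q)), M, rng)

        null = build_null(kept, None, M=n_permutations, B=n_null,
                          seed=seed, bank_fn=bank_fn)
        scores = pd.Series(scores, name="abs_effect_size")
        group = float(scores.mean())
        p = p_value(group, null, direction="greater")
        return NonDirectionalResults(
            method="Absolute Effect Size Test",
            statistic=f"|{self.stat_name}|",
            scores=scores,
            group_stat=group,
            null=null,
            pvalue=p,
            params={"seed": seed},
            dropped=dropped,
        )
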