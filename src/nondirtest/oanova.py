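"""Omnibus trial-level ANOVA (OANOVA) with participants as fixed effects.

Tests the joint null that no participant has any condition effect, by
comparing two least-squares fits at the trial level: a full model with one
intercept and one condition effect per participant (equivalently, the
participant x condition cell means) against a reduced model with
participant intercepts only.  With P participants, C=2 conditions and N
trials in total,

    F = [(SSE_reduced - SSE_full) / (P (C-1))] / [SSE_full / (N - P C)]

is referred to F(P(C-1), N - PC).  The residual-sum-of-squares form avoids
any sum-of-squares-type ambiguity and handles unbalanced cells naturally
(df2 = N - 2P).  Normality and equal within-participant variance are
assumed, as in any fixed-effects ANOVA; violations of the equal-variance
assumption can distort both sensitivity and specificity, and no robust
variant is provided here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import stats as sps

from .base import TrialModel, _fmt_p, _kv_table
from .data import PARTICIPANT, CONDITION, OUTCOME

__all__ = ["OmnibusAnova", "OanovaResults", "oanova_test"]


@dataclass
class OanovaResults:
    """OANOVA outcome: F on (df1, df2) = (P(C-1), N - PC), with the residual
    sums of squares of the full (cell means) and reduced (participant
    intercepts) fits."""

    fvalue: float
    df1: int
    df2: int
    pvalue: float
    sse_full: float
    sse_reduced: float
    n_obs: int
    n_participants: int
    params: dict = field(default_factory=dict)

    def summary(self) -> str:
        rows = [
            ("Participants:", str(self.n_participants)),
            ("Trials (total):", str(self.n_obs)),
            ("F statistic:", f"{self.fvalue:.4f}"),
            ("df:", f"({self.df1}, {self.df2})"),
            ("p-value:", _fmt_p(self.pvalue)),
            ("SSE full:", f"{self.sse_full:.6g}"),
            ("SSE reduced:", f"{self.sse_reduced:.6g}"),
        ]
        return _kv_table("Omnibus ANOVA (fixed-effects, trial level)", rows)

    def to_dict(self) -> dict:
        return {
            "method": "Omnibus ANOVA (OANOVA)",
            "F": self.fvalue,
            "df1": self.df1,
            "df2": self.df2,
            "pvalue": self.pvalue,
            "sse_full": self.sse_full,
            "sse_reduced": self.sse_reduced,
            "n_obs": self.n_obs,
            "n_participants": self.n_participants,
            "params": dict(self.params),
        }


class OmnibusAnova(TrialModel):
    """OANOVA model over a validated TrialTable (two-level condition)."""

    def fit(self) -> OanovaResults:
        df = self.data.df
        cells = df.groupby([PARTICIPANT, CONDITION], observed=True)[OUTCOME]
        if (cells.size() < 2).any():
            raise ValueError(
                "OANOVA needs >=2 trials in every participant x condition cell"
            )
        resid_full = df[OUTCOME] - cells.transform("mean")
        resid_red = df[OUTCOME] - df.groupby(PARTICIPANT)[OUTCOME].transform("mean")
        sse_full = float((resid_full**2).sum())
        sse_red = float((resid_red**2).sum())
        n = len(df)
        p = self.data.n_participants
        df1 = p  # P * (C - 1), C = 2
        df2 = n - 2 * p
        if df2 < 1:
            raise ValueError("not enough trials for the full model")
        f = ((sse_red - sse_full) / df1) / (sse_full / df2)
        pval = float(sps.f.sf(f, df1, df2))
        return OanovaResults(
            fvalue=float(f),
            df1=df1,
            df2=df2,
            pvalue=pval,
            sse_full=sse_full,
            sse_reduced=sse_red,
            n_obs=n,
            n_participants=p,
        )


def oanova_test(table) -> OanovaResults:
    """Functional form of :class:`OmnibusAnova`."""
    return OmnibusAnova(table).fit()
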