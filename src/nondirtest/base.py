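"""Model/Results base classes shared by all tests in the package.

Every test is exposed as a model object constructed from trial-level data
(a :class:`~nondirtest.data.TrialTable`, or a DataFrame plus a column
mapping via ``from_dataframe``) whose ``fit()`` returns a results object
carrying the estimates, the resampling null, the p-value and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import TrialTable, ParticipantData

__all__ = ["TrialModel", "NonDirectionalResults"]


class TrialModel:
    """Base class: holds a validated TrialTable and per-participant views."""

    def __init__(self, data: TrialTable):
        if not isinstance(data, TrialTable):
            raise TypeError(
                "data must be a TrialTable; use from_dataframe() to build one "
                "from a DataFrame with a column mapping"
            )
        self.data = data
        self.parts: list[ParticipantData] = list(data.iter_participants())

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        participant: str = "participant",
        condition: str = "condition",
        outcome: str = "outcome",
        condition2: str | None = None,
        accuracy: str | None = None,
        confidence: str | None = None,
        levels: Sequence | None = None,
        levels2: Sequence | None = None,
        **model_options,
    ):
        """Build the model from a long-format DataFrame.

        The keyword arguments name the columns holding each role;
        ``levels=(negative, positive)`` declares the condition sign
        convention.  Remaining keywords are passed to the model constructor.
        """
        columns = {"participant": participant, "condition": condition,
                   "outcome": outcome}
        if condition2 is not None:
            columns["condition2"] = condition2
        if accuracy is not None:
            columns["accuracy"] = accuracy
        if confidence is not None:
            columns["confidence"] = confidence
        table = TrialTable(df, levels=levels, levels2=levels2, columns=columns)
        return cls(table, **model_options)


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.4g}"


def _kv_table(title: str, rows: list[tuple[str, str]]) -> str:
    width = max(len(k) for k, _ in rows) + 2
    bar = "=" * max(len(title), width + 18)
    lines = [title.center(len(bar)), bar]
    lines += [f"{k:<{width}}{v}" for k, v in rows]
    lines.append(bar)
    return "\n".join(lines)


@dataclass
class NonDirectionalResults:
    """Result of a resampling-based non-directional group test.

    ``scores`` holds the per-participant statistic (a sign-consistency
    probability, or an absolute standardised effect size); the group
    statistic is their mean and is compared against the two-stage
    permutation null (``null.samples``) with a one-sided (greater) test.
    """

    method: str
    statistic: str
    scores: pd.Series
    group_stat: float
    null: "NullDistribution"  # noqa: F821 - runtime type from .permutation
    pvalue: float
    params: dict = field(default_factory=dict)
    dropped: dict = field(default_factory=dict)

    @property
    def n_participants(self) -> int:
        return len(self.scores)

    @property
    def null_quantile_95(self) -> float:
        return float(np.quantile(self.null.samples, 0.95))

    def summary(self) -> str:
        rows = [
            ("Statistic:", self.statistic),
            ("Participants:", str(self.n_participants)),
            ("Group mean:", f"{self.group_stat:.4f}"),
            ("Null mean:", f"{float(np.mean(self.null.samples)):.4f}"),
            ("Null 95th percentile:", f"{self.null_quantile_95:.4f}"),
            ("p-value (greater):", _fmt_p(self.pvalue)),
            ("Permutations/participant:", str(self.null.M)),
            ("Null samples:", str(self.null.B)),
        ]
        for k, v in self.params.items():
            rows.append((f"{k}:", str(v)))
        if self.dropped:
            rows.append(("Dropped participants:", str(len(self.dropped))))
        return _kv_table(self.method, rows)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "group_stat": self.group_stat,
            "pvalue": self.pvalue,
            "n_participants": self.n_participants,
            "scores": {str(k): float(v) for k, v in self.scores.items()},
            "params": dict(self.params),
            "dropped": {str(k): v for k, v in self.dropped.items()},
        }

    def plot_null(self, ax=None, bins=50):
        """Histogram of the permutation null with the observed group
        statistic marked (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.null.samples, bins=bins, color="0.7", density=True)
        ax.axvline(self.group_stat, color="C2", lw=2,
                   label=f"observed = {self.group_stat:.3f} (p = {_fmt_p(self.pvalue)})")
        ax.set_xlabel(f"group mean {self.statistic}")
        ax.set_ylabel("null density")
        ax.set_title(self.method)
        ax.legend()
        return ax
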