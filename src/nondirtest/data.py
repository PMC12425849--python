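"""Trial-level data container, schema validation and participant exclusion rules.

The universal input to every test in this package is a long-format table of
trials: one row per trial, with a participant identifier, a two-level
condition label (optionally a second two-level factor for interaction
contrasts), a numeric outcome (a reaction time, a confidence rating, or a
binary accuracy/response code), and optionally separate accuracy and
confidence columns for metacognition statistics.

The condition-level *order* declared at construction time defines the sign
convention of every downstream statistic: the second level is the "positive"
one, so ``mean_difference = mean(level2) - mean(level1)``.  The order is an
explicit declaration rather than file order, so that results are
reproducible across differently sorted files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialTable",
    "ParticipantData",
    "ExclusionReport",
    "SchemaError",
    "ValidationError",
    "load_trial_table",
    "apply_exclusions",
]


class SchemaError(ValueError):
    """A required column is missing or a column mapping is invalid."""


class ValidationError(ValueError):
    """The table violates the trial-level data contract."""


# canonical internal column names
PARTICIPANT = "participant"
CONDITION = "condition"
OUTCOME = "outcome"
CONDITION2 = "condition2"
ACCURACY = "accuracy"
CONFIDENCE = "confidence"

_OPTIONAL = (CONDITION2, ACCURACY, CONFIDENCE)


@dataclass
class ParticipantData:
    """All trials of one participant, in canonical arrays.

    ``cond`` (and ``cond2`` when a second factor is present) are 0/1 codes;
    code 1 is the declared positive level.  ``accuracy``/``confidence`` are
    aligned with ``y`` trial-for-trial and may be ``None``.
    """

    pid: object
    y: np.ndarray
    cond: np.ndarray
    cond2: np.ndarray | None = None
    accuracy: np.ndarray | None = None
    confidence: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return self.y.size

    def cell_values(self, level: int) -> np.ndarray:
        """Outcomes of one condition cell (``level`` is the 0/1 code)."""
        return self.y[self.cond == level]

    def cell_sizes(self) -> dict:
        """Trial counts per cell (condition, or condition x factor2)."""
        if self.cond2 is None:
            return {c: int(np.sum(self.cond == c)) for c in (0, 1)}
        return {
            (c, c2): int(np.sum((self.cond == c) & (self.cond2 == c2)))
            for c in (0, 1)
            for c2 in (0, 1)
        }

    def strata(self) -> list[np.ndarray]:
        """Index arrays of the cells used for stratified splitting."""
        if self.cond2 is None:
            return [np.flatnonzero(self.cond == c) for c in (0, 1)]
        return [
            np.flatnonzero((self.cond == c) & (self.cond2 == c2))
            for c in (0, 1)
            for c2 in (0, 1)
        ]

    def subset(self, idx: np.ndarray) -> "ParticipantData":
        return ParticipantData(
            pid=self.pid,
            y=self.y[idx],
            cond=self.cond[idx],
            cond2=None if self.cond2 is None else self.cond2[idx],
            accuracy=None if self.accuracy is None else self.accuracy[idx],
            confidence=None if self.confidence is None else self.confidence[idx],
        )

    def with_condition(self, cond: np.ndarray) -> "ParticipantData":
        """A copy with the condition labels replaced (for permutation)."""
        return ParticipantData(
            pid=self.pid,
            y=self.y,
            cond=cond,
            cond2=self.cond2,
            accuracy=self.accuracy,
            confidence=self.confidence,
        )


class TrialTable:
    """Validated long-format trial table.

    Parameters
    ----------
    df : DataFrame
        One row per trial.  Columns are mapped to the canonical names via
        ``columns``; unmapped canonical names are taken as-is when present.
    levels : sequence of 2 labels
        Declared order of the condition levels ``(negative, positive)``.
        The sign convention of every statistic follows this order.  When
        omitted, the sorted unique labels are used (and recorded).
    levels2 : sequence of 2 labels, optional
        Level order for the second factor, when present.
    columns : mapping, optional
        Maps canonical names (``participant``, ``condition``, ``outcome``,
        ``condition2``, ``accuracy``, ``confidence``) to the column names
        actually present in ``df``.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        levels: Sequence | None = None,
        levels2: Sequence | None = None,
        columns: Mapping[str, str] | None = None,
    ):
        columns = dict(columns or {})
        rename = {}
        for canon in (PARTICIPANT, CONDITION, OUTCOME, *(_OPTIONAL)):
            src = columns.get(canon, canon)
            if canon in (PARTICIPANT, CONDITION, OUTCOME) or src in df.columns:
                if src not in df.columns:
                    raise SchemaError(
                        f"required column {src!r} (mapped to {canon!r}) "
                        f"not found; available: {list(df.columns)}"
                    )
                rename[src] = canon
        data = df[list(rename)].rename(columns=rename).reset_index(drop=True)

        out = pd.to_numeric(data[OUTCOME], errors="coerce")
        bad = out.isna() & data[OUTCOME].notna()
        if bad.any():
            raise ValidationError(
                f"non-numeric outcome at row index {int(bad.idxmax())}: "
                f"{data.loc[bad.idxmax(), OUTCOME]!r}"
            )
        if out.isna().any() or not np.isfinite(out.to_numpy(float)).all():
            raise ValidationError("outcome contains missing or non-finite values")
        data[OUTCOME] = out.astype(float)

        self.levels = self._check_levels(data[CONDITION], levels, CONDITION)
        self.levels2 = (
            self._check_levels(data[CONDITION2], levels2, CONDITION2)
            if CONDITION2 in data
            else None
        )

        # every participant must populate each condition cell at least once
        counts = data.groupby([PARTICIPANT, CONDITION], observed=True).size()
        for pid in data[PARTICIPANT].unique():
            for lvl in self.levels:
                if counts.get((pid, lvl), 0) == 0:
                    raise ValidationError(
                        f"participant {pid!r} has no trials in condition {lvl!r}"
                    )
        self.df = data

    @staticmethod
    def _check_levels(col: pd.Series, levels, name: str):
        observed = pd.unique(col)
        if len(observed) != 2:
            raise ValidationError(
                f"column {name!r} must have exactly 2 levels, "
                f"found {len(observed)}: {sorted(map(str, observed))}"
            )
        if levels is None:
            levels = sorted(observed, key=str)
        levels = tuple(levels)
        if set(levels) != set(observed):
            raise ValidationError(
                f"declared levels {levels} do not match observed "
                f"levels {tuple(observed)} for {name!r}"
            )
        return levels

    # -- accessors -----------------------------------------------------
    @property
    def participants(self) -> list:
        return list(pd.unique(self.df[PARTICIPANT]))

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def __len__(self) -> int:
        return len(self.df)

    def participant_data(self, pid) -> ParticipantData:
        rows = self.df[self.df[PARTICIPANT] == pid]
        code = (rows[CONDITION] == self.levels[1]).to_numpy(int)
        code2 = None
        if self.levels2 is not None:
            code2 = (rows[CONDITION2] == self.levels2[1]).to_numpy(int)
        return ParticipantData(
            pid=pid,
            y=rows[OUTCOME].to_numpy(float),
            cond=code,
            cond2=code2,
            accuracy=rows[ACCURACY].to_numpy(float) if ACCURACY in rows else None,
            confidence=rows[CONFIDENCE].to_numpy(float) if CONFIDENCE in rows else None,
        )

    def iter_participants(self) -> Iterable[ParticipantData]:
        for pid in self.participants:
            yield self.participant_data(pid)

    def swap_sign_convention(self) -> "TrialTable":
        """The same data with the condition level order reversed."""
        return TrialTable(self.df, levels=self.levels[::-1], levels2=self.levels2)


@dataclass
class ExclusionReport:
    """Per-participant record of the eligibility screen.

    ``excluded`` is true iff any condition cell has fewer than ``min_trials``
    trials or the participant's outcome has zero variance over all their
    trials.
    """

    table: pd.DataFrame
    min_trials: int = 5

    @property
    def excluded_ids(self) -> list:
        return list(self.table.loc[self.table["excluded"], PARTICIPANT])

    @property
    def n_excluded(self) -> int:
        return int(self.table["excluded"].sum())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def __str__(self) -> str:
        kept = len(self.table) - self.n_excluded
        lines = [
            f"Exclusion screen (min {self.min_trials} trials per condition cell, "
            f"nonzero outcome variance): kept {kept}/{len(self.table)} participants."
        ]
        for _, row in self.table[self.table["excluded"]].iterrows():
            lines.append(f"  excluded {row[PARTICIPANT]!r}: {row['reason']}")
        return "\n".join(lines)


def load_trial_table(
    path,
    columns: Mapping[str, str] | None = None,
    levels: Sequence | None = None,
    levels2: Sequence | None = None,
    sep: str | None = None,
) -> TrialTable:
    """Read a delimited text file (CSV/TSV, header required) into a TrialTable.

    ``sep=None`` sniffs the delimiter.  ``columns`` maps canonical names to
    the file's column names, e.g. ``{"participant": "subj", "outcome": "rt"}``.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    return TrialTable(df, levels=levels, levels2=levels2, columns=columns)


def apply_exclusions(
    table: TrialTable, min_trials: int = 5
) -> tuple[TrialTable, ExclusionReport]:
    """Apply the participant eligibility rules.

    A participant is excluded when any condition cell (condition, or
    condition x second factor, when present) holds fewer than ``min_trials``
    trials, or when their outcome is constant over all their trials.
    Returns the retained table and a per-participant report.
    """
    records = []
    keep = []
    for part in table.iter_participants():
        sizes = part.cell_sizes()
        var = float(np.var(part.y))
        reasons = []
        if any(n < min_trials for n in sizes.values()):
            reasons.append("min_trials")
        if var == 0.0:
            reasons.append("zero_variance")
        rec = {
            PARTICIPANT: part.pid,
            "n_trials": part.n_trials,
            "min_cell_count": min(sizes.values()),
            "outcome_variance": var,
            "excluded": bool(reasons),
            "reason": "+".join(reasons),
        }
        records.append(rec)
        if not reasons:
            keep.append(part.pid)
    report = ExclusionReport(pd.DataFrame.from_records(records), min_trials=min_trials)
    if not keep:
        raise ValidationError(
            "empty analysis set: all participants excluded by the eligibility rules"
        )
    kept_df = table.df[table.df[PARTICIPANT].isin(keep)].reset_index(drop=True)
    return TrialTable(kept_df, levels=table.levels, levels2=table.levels2), report
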