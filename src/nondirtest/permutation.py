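"""Within-participant label-permutation machinery and null construction.

Both non-directional tests share the same two-stage null distribution
(Stelzer-style aggregation): first, for every participant, a bank of M
statistic values is computed on datasets whose condition labels were
shuffled within that participant (breaking any condition/outcome
correlation while preserving per-condition trial counts); second, B
group-level null samples are drawn, each the mean over participants of one
value sampled (with replacement) from each participant's bank.

One master seed deterministically spawns an independent stream per
participant (keyed by the participant's position in a stable sort of the
identifiers, so results do not depend on row order in the input file) plus
one stream for the group-level resampling stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ParticipantData

__all__ = ["NullDistribution", "permute_labels", "permuted_stat_bank",
           "build_null", "p_value", "participant_rngs", "as_seed_sequence"]


def as_seed_sequence(seed) -> np.random.SeedSequence:
    """Coerce an int/None/SeedSequence into a SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def participant_rngs(seed, pids) -> tuple[dict, np.random.Generator]:
    """Spawn one Generator per participant plus one for group resampling.

    Streams are keyed by each participant's rank in a stable (string) sort
    of the identifiers, so the same seed gives the same stream to the same
    participant regardless of row order.
    """
    order = sorted(range(len(pids)), key=lambda i: str(pids[i]))
    master = as_seed_sequence(seed)
    children = master.spawn(len(pids) + 1)
    rngs = {}
    for rank, i in enumerate(order):
        rngs[pids[i]] = np.random.default_rng(children[rank])
    return rngs, np.random.default_rng(children[-1])


def permute_labels(part: ParticipantData, rng: np.random.Generator) -> ParticipantData:
    """Shuffle the condition labels of one participant's trials.

    Per-condition counts are preserved and outcomes untouched.  When a
    second factor is present the labels are shuffled within each level of
    that factor, so all four cell counts are preserved as well.
    """
    if np.all(part.cond == part.cond[0]):
        raise ValueError(f"participant {part.pid!r}: needs trials in both conditions")
    if part.cond2 is None:
        new = rng.permutation(part.cond)
    else:
        new = part.cond.copy()
        for level in (0, 1):
            idx = np.flatnonzero(part.cond2 == level)
            new[idx] = rng.permutation(part.cond[idx])
    return part.with_condition(new)


def permuted_stat_bank(
    part: ParticipantData, stat_fn, M: int, rng: np.random.Generator
) -> np.ndarray:
    """M values of ``stat_fn`` on independently label-shuffled copies of one
    participant's trials.  Repeated permutations are permitted (they occur
    with non-negligible probability only for very small trial counts)."""
    return np.array([stat_fn(permute_labels(part, rng)) for _ in range(M)])


@dataclass
class NullDistribution:
    """Two-stage permutation null of a group-mean statistic.

    ``banks`` maps participant id -> M per-participant permuted statistic
    values; ``samples`` holds the B group-level null means.
    """

    banks: dict
    samples: np.ndarray
    M: int
    B: int
    seed: object = None

    def __post_init__(self):
        assert self.samples.size == self.B
        for pid, bank in self.banks.items():
            assert bank.size == self.M, f"bank of {pid!r} has {bank.size} != M entries"


def build_null(
    parts: list[ParticipantData],
    stat_fn,
    M: int = 100,
    B: int = 10_000,
    seed=None,
    bank_fn=None,
) -> NullDistribution:
    """Construct the two-stage permutation null for a list of participants.

    ``stat_fn`` maps a ParticipantData to a real number.  ``bank_fn``, when
    given, must map ``(part, M, rng)`` to an array of M permuted-statistic
    values and is used as a vectorised fast path; otherwise each bank is
    built by M explicit label shuffles.
    """
    if M < 1 or B < 1:
        raise ValueError("M and B must be >= 1")
    if not parts:
        raise ValueError("no participants")
    rngs, group_rng = participant_rngs(seed, [p.pid for p in parts])
    banks = {}
    for part in parts:
        rng = rngs[part.pid]
        if bank_fn is not None:
            banks[part.pid] = np.asarray(bank_fn(part, M, rng), float)
        else:
            banks[part.pid] = permuted_stat_bank(part, stat_fn, M, rng)
    # stage two: each group sample averages one bank draw per participant;
    # draws happen in stable-sorted id order so row order cannot matter
    total = np.zeros(B)
    for pid in sorted(banks, key=str):
        idx = group_rng.integers(0, M, size=B)
        total += banks[pid][idx]
    samples = total / len(parts)
    return NullDistribution(banks=banks, samples=samples, M=M, B=B, seed=seed)


def p_value(observed: float, null: NullDistribution, direction: str = "greater") -> float:
    """Permutation p-value with the add-one correction:
    ``(1 + #{null samples at least as extreme}) / (B + 1)``."""
    s = null.samples
    tol = 1e-12 * max(1.0, abs(observed))
    if direction == "greater":
        hits = int(np.sum(s >= observed - tol))
    elif direction == "less":
        hits = int(np.sum(s <= observed + tol))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return float((1 + hits) / (null.B + 1))
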