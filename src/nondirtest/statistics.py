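"""Per-participant signed summary statistics and the directional filter test.

Each statistic maps one participant's trials to a single finite real number
with a defined sign convention: swapping the two condition levels flips the
sign.  Statistics are registered by name so that the resampling tests can be
pointed at any of them (`mean_diff`, `cohen_d`, `dprime_diff`, `phi`,
`auroc2_diff`, `interaction_contrast`).

The directional sign-flipping test at the bottom is the group-level filter
used to separate directional from non-directional effects: it permutes the
signs of per-participant effects to build the null of a zero population
mean.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy import stats as sps

from .data import ParticipantData

__all__ = [
    "UndefinedStatisticError",
    "STATISTICS",
    "get_statistic",
    "mean_difference",
    "cohen_d",
    "dprime",
    "phi",
    "phi_counts",
    "type2_auroc",
    "auroc2_difference",
    "interaction_contrast",
    "directional_sign_flip_test",
]


class UndefinedStatisticError(ValueError):
    """The statistic has no defined value on this participant's data
    (e.g. a response cell with no incorrect trials for the type-2 AUROC);
    the participant should be dropped for this statistic, with a logged
    reason, rather than the analysis aborted."""


def _cells(part: ParticipantData) -> tuple[np.ndarray, np.ndarray]:
    y0, y1 = part.y[part.cond == 0], part.y[part.cond == 1]
    if y0.size == 0 or y1.size == 0:
        raise ValueError(f"participant {part.pid!r}: empty condition cell")
    return y0, y1


def mean_difference(part: ParticipantData) -> float:
    """mean(outcome | positive level) - mean(outcome | negative level)."""
    y0, y1 = _cells(part)
    return float(y1.mean() - y0.mean())


def cohen_d(part: ParticipantData) -> float:
    """Two-sample Cohen's d: mean difference over the pooled SD.

    The pooled SD weights the cell variances by their degrees of freedom
    (per-cell Bessel correction), the conventional two-sample form.
    """
    y0, y1 = _cells(part)
    if y0.size < 2 or y1.size < 2:
        raise ValueError(
            f"participant {part.pid!r}: Cohen's d needs >=2 trials per condition"
        )
    n0, n1 = y0.size, y1.size
    sp2 = ((n0 - 1) * y0.var(ddof=1) + (n1 - 1) * y1.var(ddof=1)) / (n0 + n1 - 2)
    if sp2 == 0.0:
        raise ValueError(
            f"participant {part.pid!r}: zero pooled SD "
            "(participant should have been excluded)"
        )
    return float((y1.mean() - y0.mean()) / np.sqrt(sp2))


def _rate_z(k: int, n: int) -> float:
    # extreme rates 0 and 1 are pulled in by the standard 1/(2N) correction
    p = k / n
    if p == 0.0:
        p = 1.0 / (2 * n)
    elif p == 1.0:
        p = 1.0 - 1.0 / (2 * n)
    return float(sps.norm.ppf(p))


def dprime(part: ParticipantData) -> float:
    """Signal-detection sensitivity difference between the two condition cells.

    Treats the positive-level cell as the signal class and the negative-level
    cell as the noise class of binary responses: z(rate_1) - z(rate_0), i.e.
    z(hit rate) - z(false-alarm rate), with extreme rates replaced by 1/(2N)
    and 1 - 1/(2N).
    """
    y0, y1 = _cells(part)
    vals = set(np.unique(np.concatenate([y0, y1])))
    if not vals <= {0.0, 1.0}:
        raise ValueError(f"participant {part.pid!r}: d' requires binary outcomes")
    return _rate_z(int(y1.sum()), y1.size) - _rate_z(int(y0.sum()), y0.size)


def phi_counts(a: float, b: float, c: float, d: float) -> float:
    """Phi coefficient of the 2x2 table [[a, b], [c, d]]: (ad-bc)/sqrt of
    the product of the four margins.  Errors on a zero margin."""
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError(f"phi undefined: zero margin in table ({a},{b},{c},{d})")
    return float((a * d - b * c) / np.sqrt(np.prod([float(m) for m in margins])))


def phi(part: ParticipantData) -> float:
    """Phi for the condition x binary-outcome 2x2 table of one participant.

    Rows are the condition levels (positive level first), columns the binary
    outcome (1 first); swapping the condition sign convention flips the sign.
    """
    y0, y1 = _cells(part)
    vals = set(np.unique(np.concatenate([y0, y1])))
    if not vals <= {0.0, 1.0}:
        raise ValueError(f"participant {part.pid!r}: phi requires binary outcomes")
    a, b = float(y1.sum()), float(y1.size - y1.sum())
    c, d = float(y0.sum()), float(y0.size - y0.sum())
    return phi_counts(a, b, c, d)


def type2_auroc(correct: np.ndarray, confidence: np.ndarray) -> float:
    """Area under the type-2 ROC: confidence discriminating correct from
    incorrect trials.

    Computed as the Mann-Whitney probability P(conf_correct > conf_incorrect)
    with half credit for ties, which equals the trapezoidal area under the
    ROC built over the observed confidence levels as criteria.
    """
    correct = np.asarray(correct, bool)
    conf = np.asarray(confidence, float)
    pos, neg = conf[correct], conf[~correct]
    if pos.size == 0 or neg.size == 0:
        raise UndefinedStatisticError(
            "type-2 AUROC undefined: need both correct and incorrect trials"
        )
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def auroc2_difference(part: ParticipantData) -> float:
    """Metacognitive-sensitivity contrast: AUROC2 conditioned on the positive
    response minus AUROC2 conditioned on the negative response.

    The condition factor plays the role of the conditioning response; the
    accuracy and confidence columns supply the type-2 classification.
    Undefined (raises) when either response cell lacks correct or incorrect
    trials — callers should drop the participant with a logged reason.
    """
    if part.accuracy is None or part.confidence is None:
        raise ValueError(
            f"participant {part.pid!r}: auroc2_diff needs accuracy and "
            "confidence columns"
        )
    out = []
    for level in (1, 0):
        m = part.cond == level
        out.append(type2_auroc(part.accuracy[m], part.confidence[m]))
    return float(out[0] - out[1])


def interaction_contrast(part: ParticipantData) -> float:
    """Difference of simple effects on cell means for a 2x2 within design:
    (mean(B+|A+) - mean(B-|A+)) - (mean(B+|A-) - mean(B-|A-)),
    where A is the primary condition factor and B the second factor."""
    if part.cond2 is None:
        raise ValueError(
            f"participant {part.pid!r}: interaction_contrast needs a second factor"
        )
    means = {}
    for a, b in product((0, 1), (0, 1)):
        cell = part.y[(part.cond == a) & (part.cond2 == b)]
        if cell.size == 0:
            raise ValueError(
                f"participant {part.pid!r}: empty cell (condition={a}, factor2={b})"
            )
        means[a, b] = cell.mean()
    return float((means[1, 1] - means[1, 0]) - (means[0, 1] - means[0, 0]))


STATISTICS = {
    "mean_diff": mean_difference,
    "cohen_d": cohen_d,
    "dprime_diff": dprime,
    "phi": phi,
    "auroc2_diff": auroc2_difference,
    "interaction_contrast": interaction_contrast,
}

#: minimum trials per condition cell each statistic needs
MIN_TRIALS_PER_CELL = {
    "mean_diff": 1,
    "cohen_d": 2,
    "dprime_diff": 1,
    "phi": 1,
    "auroc2_diff": 1,
    "interaction_contrast": 1,
}


def get_statistic(name):
    """Resolve a statistic by registry name, or pass a callable through."""
    if callable(name):
        return name
    try:
        return STATISTICS[name]
    except KeyError:
        raise KeyError(
            f"unknown statistic {name!r}; available: {sorted(STATISTICS)}"
        ) from None


def directional_sign_flip_test(
    effects,
    n_flips: int = 10_000,
    seed=None,
    exhaustive_limit: int = 15,
) -> float:
    """Two-sided sign-flipping test of a zero population mean.

    Randomly negates each participant's effect and compares |mean| of each
    flip pattern with the observed |mean|.  All ``2^n`` patterns are
    enumerated when ``n <= exhaustive_limit`` (the p-value is then exact:
    the identity pattern is among them); otherwise ``n_flips`` Monte-Carlo
    patterns are drawn and the add-one correction applied.
    """
    effects = np.asarray(effects, float)
    n = effects.size
    if n < 2:
        raise ValueError("sign-flip test needs at least 2 participants")
    if n_flips < 1:
        raise ValueError("n_flips must be >= 1")
    observed = abs(effects.mean())
    if n <= exhaustive_limit:
        signs = np.array(list(product((-1.0, 1.0), repeat=n)))
        null = np.abs(signs @ effects) / n
        return float(np.mean(null >= observed - 1e-12))
    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_flips, n))
    null = np.abs(signs @ effects) / n
    hits = int(np.sum(null >= observed - 1e-12))
    return float((1 + hits) / (n_flips + 1))
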