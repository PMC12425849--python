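"""Prevalence global-null test (GNT).

Two-stage procedure: each participant's condition effect is first tested at
level ``alpha_individual`` (a two-sided two-sample t-test by default, or a
within-participant label-permutation test for outcomes where t is not
appropriate).  The count k of significant participants out of n is then
tested against the binomial Bin(n, alpha_individual) expected under the
global null — the hypothesis that no single participant has any true
effect — with a one-sided binomial test, at level ``alpha_prevalence``.

Because the test is one-sided, the confidence interval on the population
prevalence always includes 100%; the informative end is the lower bound,
obtained by one-sided Clopper-Pearson inversion: the smallest prevalence
pi with P(X >= k | n, pi) >= alpha_prevalence.  The global null is
rejected exactly when the lower bound exceeds alpha_individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .base import TrialModel, _fmt_p, _kv_table
from .data import ParticipantData
from .statistics import get_statistic

__all__ = ["PrevalenceTest", "PrevalenceResults", "individual_test",
           "prevalence_test"]


def individual_test(
    part: ParticipantData,
    statistic="mean_diff",
    method: str = "t",
    alpha_individual: float = 0.05,
    n_permutations: int = 10_000,
    seed=None,
    exhaustive_limit: int = 20_000,
) -> tuple[float, bool]:
    """Two-sided individual-level test of one participant's condition effect.

    ``method="t"``: two-sample t-test on the outcome between conditions
    (continuous outcomes).  ``method="permutation"``: label-permutation test
    on the chosen statistic, exhaustive over all label assignments when
    their number is at most ``exhaustive_limit``.
    Returns ``(p, p < alpha_individual)``.
    """
    y0 = part.y[part.cond == 0]
    y1 = part.y[part.cond == 1]
    if method == "t":
        if y0.size < 2 or y1.size < 2:
            raise ValueError(
                f"participant {part.pid!r}: t-test needs >=2 trials per condition"
            )
        if np.var(y0) == 0 and np.var(y1) == 0:
            raise ValueError(
                f"participant {part.pid!r}: degenerate variance; "
                "use method='permutation'"
            )
        p = float(sps.ttest_ind(y1, y0).pvalue)
    elif method == "permutation":
        stat = get_statistic(statistic)
        observed = abs(stat(part))
        n, n1 = part.n_trials, int(part.cond.sum())
        tol = 1e-12 * max(1.0, observed)
        if comb(n, n1) <= exhaustive_limit and part.cond2 is None:
            hits = total = 0
            base = np.zeros(n, dtype=part.cond.dtype)
            for pos in combinations(range(n), n1):
                lab = base.copy()
                lab[list(pos)] = 1
                total += 1
                if abs(stat(part.with_condition(lab))) >= observed - tol:
                    hits += 1
            p = hits / total
        else:
            from .permutation import permute_labels

            rng = np.random.default_rng(seed)
            hits = sum(
                abs(stat(permute_labels(part, rng))) >= observed - tol
                for _ in range(n_permutations)
            )
            p = (1 + hits) / (n_permutations + 1)
        p = float(p)
    else:
        raise ValueError(f"unknown method {method!r}")
    return p, p < alpha_individual


def prevalence_test(
    flags,
    alpha_individual: float = 0.05,
    alpha_prevalence: float = 0.05,
    pvalues=None,
) -> "PrevalenceResults":
    """Binomial global-null test from per-participant significance flags.

    ``p = P(X >= k | n, alpha_individual)`` and the one-sided
    (1 - alpha_prevalence) Clopper-Pearson lower bound on prevalence.
    """
    flags = np.asarray(flags, bool)
    n, k = flags.size, int(flags.sum())
    if n < 1:
        raise ValueError("need at least one participant")
    p = float(sps.binom.sf(k - 1, n, alpha_individual))
    # smallest pi with P(X >= k | n, pi) >= alpha_prevalence
    if k == 0:
        lower = 0.0
    else:
        lower = float(sps.beta.ppf(alpha_prevalence, k, n - k + 1))
    return PrevalenceResults(
        n=n,
        k=k,
        alpha_individual=alpha_individual,
        alpha_prevalence=alpha_prevalence,
        pvalue=p,
        ci_lower=lower,
        individual_pvalues=None if pvalues is None else pd.Series(pvalues),
    )


@dataclass
class PrevalenceResults:
    """GNT outcome: significant count, binomial p, one-sided prevalence CI.

    The CI upper bound is 1 by construction; ``reject`` (global null
    rejected at ``alpha_prevalence``) is equivalent to the CI lower bound
    exceeding ``alpha_individual``.
    """

    n: int
    k: int
    alpha_individual: float
    alpha_prevalence: float
    pvalue: float
    ci_lower: float
    individual_pvalues: pd.Series | None = None
    params: dict = field(default_factory=dict)

    @property
    def prevalence(self) -> float:
        return self.k / self.n

    @property
    def ci_upper(self) -> float:
        return 1.0

    @property
    def reject(self) -> bool:
        return self.pvalue < self.alpha_prevalence

    def summary(self) -> str:
        rows = [
            ("Participants:", str(self.n)),
            ("Significant at alpha_ind:", str(self.k)),
            ("Observed prevalence:", f"{100 * self.prevalence:.0f}%"),
            ("One-sided 95% CI:",
             f"[{100 * self.ci_lower:.0f}%, 100%]"),
            ("Binomial p-value:", _fmt_p(self.pvalue)),
            ("alpha_individual:", str(self.alpha_individual)),
            ("alpha_prevalence:", str(self.alpha_prevalence)),
            ("Global null rejected:", str(self.reject)),
        ]
        return _kv_table("Prevalence Global-Null Test (GNT)", rows)

    def to_dict(self) -> dict:
        out = {
            "method": "Prevalence Global-Null Test (GNT)",
            "n_participants": self.n,
            "k_significant": self.k,
            "prevalence": self.prevalence,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "pvalue": self.pvalue,
            "alpha_individual": self.alpha_individual,
            "alpha_prevalence": self.alpha_prevalence,
            "reject": bool(self.reject),
            "params": dict(self.params),
        }
        if self.individual_pvalues is not None:
            out["individual_pvalues"] = {
                str(k): float(v) for k, v in self.individual_pvalues.items()
            }
        return out


class PrevalenceTest(TrialModel):
    """GNT model: individual-level tests, then the binomial prevalence test.

    Parameters
    ----------
    data : TrialTable
    statistic : str, default "mean_diff"
        Statistic for the permutation individual test (ignored by ``"t"``).
    method : {"t", "permutation"}, default "t"
        Individual-level test; "t" is appropriate for continuous outcomes.
    """

    def __init__(self, data, statistic="mean_diff", method: str = "t"):
        super().__init__(data)
        self.statistic = statistic
        self.method = method

    def fit(
        self,
        alpha_individual: float = 0.05,
        alpha_prevalence: float = 0.05,
        n_permutations: int = 10_000,
        seed=None,
    ) -> PrevalenceResults:
        from .permutation import as_seed_sequence

        master = as_seed_sequence(seed)
        children = master.spawn(len(self.parts))
        pvals = {}
        order = {pid: rank for rank, pid in
                 enumerate(sorted((p.pid for p in self.parts), key=str))}
        for part in self.parts:
            p, _ = individual_test(
                part,
                statistic=self.statistic,
                method=self.method,
                alpha_individual=alpha_individual,
                n_permutations=n_permutations,
                seed=children[order[part.pid]],
            )
            pvals[part.pid] = p
        pvals = pd.Series(pvals, name="individual_pvalue")
        res = prevalence_test(
            (pvals < alpha_individual).to_numpy(),
            alpha_individual=alpha_individual,
            alpha_prevalence=alpha_prevalence,
            pvalues=pvals,
        )
        res.params = {"method": self.method, "statistic": self.statistic,
                      "seed": seed}
        return res
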