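"""Generative simulator for non-directional within-participant effects, and
Monte-Carlo estimation of power and type-I error for every test.

The generative model is a standard two-condition (congruent/incongruent)
priming experiment.  Each participant i has a latent true effect
e_i ~ N(0, sigma_b); trial outcomes are

    y = c * e_i + eps,    eps ~ N(0, sigma_w),  c in {0, 1},

with c = 1 for the incongruent condition.  Two named scenarios are used
throughout:

* ``non_directional``: sigma_b = 15, sigma_w = 30 — every participant has a
  true effect, but signs and magnitudes vary, so the group mean is near
  zero and directional tests fail;
* ``global_null``: sigma_b = 0, sigma_w = 100 — no participant has any
  effect.

Both use 15 participants and 100 trials per condition by default.  Outcomes
carry no baseline offset (the tests are location-invariant; a nonzero
``baseline`` can be added for display purposes only).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .absolute_es import AbsoluteEffectSize
from .data import TrialTable
from .oanova import OmnibusAnova
from .prevalence import PrevalenceTest
from .sign_consistency import SignConsistency

__all__ = [
    "ScenarioParams",
    "SimulatedDataset",
    "simulate_scenario",
    "OperatingCharacteristics",
    "estimate_operating_characteristics",
    "TEST_REGISTRY",
]

CONDITION_LEVELS = ("congruent", "incongruent")  # incongruent is c=1 (positive)


@dataclass(frozen=True)
class ScenarioParams:
    """Generative-model parameters.

    sigma_b : between-participant SD of the true effects e_i (outcome units)
    sigma_w : within-participant trial SD (outcome units)
    n_participants, n_trials : participants, and trials per condition
    baseline : constant added to every outcome (display only; default 0)
    seed : default seed used when none is passed to simulate_scenario
    """

    sigma_b: float
    sigma_w: float
    n_participants: int = 15
    n_trials: int = 100
    baseline: float = 0.0
    seed: object = None

    def __post_init__(self):
        if self.sigma_b < 0 or self.sigma_w <= 0:
            raise ValueError("need sigma_b >= 0 and sigma_w > 0")
        if self.n_participants < 1 or self.n_trials < 1:
            raise ValueError("need n_participants >= 1 and n_trials >= 1")

    @classmethod
    def non_directional(cls, **kw) -> "ScenarioParams":
        """True effects in every participant, heterogeneous in sign."""
        return cls(sigma_b=15.0, sigma_w=30.0, **kw)

    @classmethod
    def global_null(cls, **kw) -> "ScenarioParams":
        """No participant has any true effect."""
        return cls(sigma_b=0.0, sigma_w=100.0, **kw)

    def replace(self, **kw) -> "ScenarioParams":
        return replace(self, **kw)


@dataclass
class SimulatedDataset:
    """A simulated TrialTable plus the latent per-participant true effects."""

    table: TrialTable
    true_effects: pd.Series
    params: ScenarioParams

    @property
    def df(self) -> pd.DataFrame:
        return self.table.df


def simulate_scenario(params: ScenarioParams, seed=None) -> SimulatedDataset:
    """Draw one dataset from the generative model.

    Per participant: e_i ~ N(0, sigma_b); congruent outcomes are pure noise
    N(baseline, sigma_w); incongruent outcomes add e_i.  Deterministic given
    the seed (``seed`` overrides ``params.seed``).
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n_p, n_t = params.n_participants, params.n_trials
    pids = [f"P{i + 1:03d}" for i in range(n_p)]
    effects = rng.normal(0.0, params.sigma_b, size=n_p) if params.sigma_b > 0 \
        else np.zeros(n_p)
    frames = []
    for pid, e in zip(pids, effects):
        noise = rng.normal(0.0, params.sigma_w, size=2 * n_t)
        y = params.baseline + noise
        y[n_t:] += e  # second block is the incongruent condition
        frames.append(pd.DataFrame({
            "participant": pid,
            "condition": np.repeat(CONDITION_LEVELS, n_t),
            "outcome": y,
        }))
    df = pd.concat(frames, ignore_index=True)
    table = TrialTable(df, levels=CONDITION_LEVELS)
    return SimulatedDataset(
        table=table,
        true_effects=pd.Series(effects, index=pids, name="true_effect"),
        params=params,
    )


def _run_sign_consistency(table, alpha, seed, n_splits=500, n_permutations=100,
                          n_null=10_000, statistic="mean_diff"):
    res = SignConsistency(table, statistic=statistic, n_splits=n_splits).fit(
        n_permutations=n_permutations, n_null=n_null, seed=seed)
    return res.pvalue < alpha


def _run_absolute_es(table, alpha, seed, n_permutations=100, n_null=10_000,
                     statistic="cohen_d"):
    res = AbsoluteEffectSize(table, statistic=statistic).fit(
        n_permutations=n_permutations, n_null=n_null, seed=seed)
    return res.pvalue < alpha


def _run_prevalence(table, alpha, seed, alpha_individual=0.05, method="t",
                    statistic="mean_diff"):
    res = PrevalenceTest(table, statistic=statistic, method=method).fit(
        alpha_individual=alpha_individual, alpha_prevalence=alpha, seed=seed)
    return res.pvalue < alpha


def _run_oanova(table, alpha, seed):
    return OmnibusAnova(table).fit().pvalue < alpha


TEST_REGISTRY = {
    "sign_consistency": _run_sign_consistency,
    "absolute_es": _run_absolute_es,
    "prevalence": _run_prevalence,
    "oanova": _run_oanova,
}


@dataclass
class OperatingCharacteristics:
    """Monte-Carlo rejection proportion with an exact (Clopper-Pearson)
    95% binomial CI.  With sigma_b = 0 the proportion estimates the type-I
    error; otherwise it estimates power."""

    test: str
    params: ScenarioParams
    alpha: float
    n_sims: int
    n_reject: int

    @property
    def rejection_rate(self) -> float:
        return self.n_reject / self.n_sims

    @property
    def ci(self) -> tuple[float, float]:
        k, n = self.n_reject, self.n_sims
        lo = 0.0 if k == 0 else float(sps.beta.ppf(0.025, k, n - k + 1))
        hi = 1.0 if k == n else float(sps.beta.ppf(0.975, k + 1, n - k))
        return lo, hi

    def to_dict(self) -> dict:
        lo, hi = self.ci
        return {
            "test": self.test,
            "sigma_b": self.params.sigma_b,
            "sigma_w": self.params.sigma_w,
            "n_participants": self.params.n_participants,
            "n_trials": self.params.n_trials,
            "alpha": self.alpha,
            "n_sims": self.n_sims,
            "rejection_rate": self.rejection_rate,
            "ci95": [lo, hi],
        }


def estimate_operating_characteristics(
    test: str,
    params: ScenarioParams,
    n_sims: int = 1000,
    alpha: float = 0.05,
    seed=None,
    **test_options,
) -> OperatingCharacteristics:
    """Rejection proportion of a named test over fresh simulated datasets.

    Each replicate draws new latent effects e_i and new trial noise.  The
    test identifier is one of ``TEST_REGISTRY``; extra keyword arguments
    (e.g. ``n_null=1000`` to shrink the permutation null for speed) are
    forwarded to the test runner.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    try:
        runner = TEST_REGISTRY[test]
    except KeyError:
        raise KeyError(
            f"unknown test {test!r}; available: {sorted(TEST_REGISTRY)}"
        ) from None
    master = np.random.SeedSequence(seed)
    n_reject = 0
    for child in master.spawn(n_sims):
        data_seed, test_seed = child.spawn(2)
        sim = simulate_scenario(params, seed=data_seed)
        if runner(sim.table, alpha, test_seed, **test_options):
            n_reject += 1
    return OperatingCharacteristics(
        test=test, params=params, alpha=alpha, n_sims=n_sims, n_reject=n_reject
    )
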