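"""2AFC scoring and frequentist / Bayesian tests against chance.

Recognition of the exposed triples is probed with 16 two-alternative
forced-choice trials; a correct response picks the member of the exposure
(STAT) set, so chance is 8/16 = 50%. Group performance is tested against
chance with the one-sample Wilcoxon signed-rank statistic (the V reported
by R), groups are compared with the rank-sum (Mann-Whitney) test, and null
results are quantified with the JZS Bayes factor: the default-prior t-test
Bayes factor obtained by integrating the noncentral-t likelihood over a
Cauchy(0, r) prior on the standardised effect size, r = sqrt(2)/2.
BF10 > 3 counts as substantial evidence for an effect, BF10 < 1/3 for the
null, anything between as inconclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .stimuli import AFCTest

__all__ = [
    "AFCResult",
    "BayesReport",
    "score_2afc",
    "wilcoxon_vs_chance",
    "mann_whitney_groups",
    "jzs_bf_one_sample",
    "jzs_bf_independent",
    "bf_verdict",
]

JASP_DEFAULT_PRIOR = np.sqrt(2.0) / 2.0  # Cauchy scale of the default prior


@dataclass
class AFCResult:
    subject: str
    n_correct: int
    percent: float
    responses: list
    group: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_correct <= 16:
            raise ValueError("n_correct must lie in 0..16")


def score_2afc(responses, key: AFCTest, subject: str = "", group: str | None = None) -> AFCResult:
    """Score chosen triples against the trial list.

    ``responses`` holds, per trial, either the chosen triple (tuple of tone
    names) or the index 0/1 of the chosen interval (0 = played first).
    """
    if len(responses) != len(key.trials):
        raise ValueError("one response per trial required")
    n_correct = 0
    for resp, (stat_triple, test_triple), stat_first in zip(
        responses, key.trials, key.order_flags
    ):
        if isinstance(resp, (int, np.integer)):
            chosen = (stat_triple if stat_first else test_triple) if resp == 0 else (
                test_triple if stat_first else stat_triple
            )
        else:
            chosen = tuple(resp)
            if chosen not in (stat_triple, test_triple):
                raise ValueError(f"response {chosen} matches neither trial member")
        if chosen == stat_triple:
            n_correct += 1
    return AFCResult(
        subject=subject,
        group=group,
        n_correct=n_correct,
        percent=n_correct / 16.0 * 100.0,
        responses=list(responses),
    )


def wilcoxon_vs_chance(scores, chance: float = 50.0) -> dict:
    """One-sample Wilcoxon signed-rank test of scores against chance.

    Returns V (the sum of positive ranks, R's convention) and the two-sided
    p-value; exact-chance scores are dropped per the signed-rank convention.
    """
    d = np.asarray(scores, dtype=float) - chance
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all scores equal chance; the test carries no information")
    ranks = stats.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    res = stats.wilcoxon(d, alternative="two-sided")
    return {"V": v, "p": float(res.pvalue), "n": int(d.size)}


def mann_whitney_groups(a, b) -> dict:
    """Independent rank-sum comparison of two score lists (ties mid-ranked)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {"W": float(res.statistic), "p": float(res.pvalue)}


def bf_verdict(bf10: float) -> str:
    if bf10 > 3.0:
        return "supports H1"
    if bf10 < 1.0 / 3.0:
        return "supports H0"
    return "inconclusive"


@dataclass
class BayesReport:
    bf10: float
    prior_scale: float
    verdict: str
    t: float
    n: int
    alternative: str

    def __post_init__(self) -> None:
        if self.bf10 <= 0:
            raise ValueError("a Bayes factor is positive")


def _jzs_bf(t: float, df: float, n_eff: float, r: float, alternative: str) -> float:
    """JZS Bayes factor by quadrature over the effect-size prior.

    Marginal likelihood under H1 integrates the noncentral-t density of the
    observed t over delta ~ Cauchy(0, r) (halved and doubled on the positive
    axis for the unilateral test); H0 is the central t density.
    """

    def like(delta: float) -> float:
        return stats.nct.pdf(t, df, delta * np.sqrt(n_eff))

    prior = stats.cauchy(loc=0.0, scale=r)
    if alternative == "greater":
        integrand = lambda d: like(d) * 2.0 * prior.pdf(d)
        m1, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    elif alternative == "less":
        integrand = lambda d: like(d) * 2.0 * prior.pdf(d)
        m1, _ = integrate.quad(integrand, -np.inf, 0.0, limit=200)
    elif alternative == "two-sided":
        integrand = lambda d: like(d) * prior.pdf(d)
        lo, _ = integrate.quad(integrand, -np.inf, 0.0, limit=200)
        hi, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
        m1 = lo + hi
    else:
        raise ValueError("alternative must be 'two-sided', 'greater' or 'less'")
    m0 = stats.t.pdf(t, df)
    return float(m1 / m0)


def jzs_bf_one_sample(
    scores,
    null_value: float = 50.0,
    prior_scale: float = JASP_DEFAULT_PRIOR,
    alternative: str = "greater",
) -> BayesReport:
    """JZS one-sample t-test Bayes factor against ``null_value``.

    The default is unilateral in the learning direction (scores above
    chance), matching how above-chance recognition is tested.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate (zero-variance) scores")
    n = x.size
    t = (x.mean() - null_value) / (sd / np.sqrt(n))
    bf10 = _jzs_bf(t, df=n - 1, n_eff=n, r=prior_scale, alternative=alternative)
    return BayesReport(
        bf10=bf10,
        prior_scale=prior_scale,
        verdict=bf_verdict(bf10),
        t=float(t),
        n=n,
        alternative=alternative,
    )


def jzs_bf_independent(
    a,
    b,
    prior_scale: float = JASP_DEFAULT_PRIOR,
    alternative: str = "two-sided",
) -> BayesReport:
    """JZS independent-samples t-test Bayes factor for a group difference."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 observations per group")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise ValueError("degenerate (zero-variance) groups")
    n_eff = na * nb / (na + nb)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    bf10 = _jzs_bf(t, df=na + nb - 2, n_eff=n_eff, r=prior_scale, alternative=alternative)
    return BayesReport(
        bf10=bf10,
        prior_scale=prior_scale,
        verdict=bf_verdict(bf10),
        t=float(t),
        n=na + nb,
        alternative=alternative,
    )
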