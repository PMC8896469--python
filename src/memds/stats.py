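"""Exact statistics for small-count mutation data.

Everything a rate comparison in this package needs is implemented here from
first principles: exact hypergeometric (Fisher) tests, conditional-MLE odds
ratio bounds from the noncentral hypergeometric likelihood, Clopper-Pearson
binomial intervals with a Poisson/gamma path for astronomically large
denominators, exact/approximate rank-sum tests, a k-sample equal-proportion
test and a Monte-Carlo multinomial omnibus test against externally supplied
expected rates.  scipy supplies distribution primitives (log-gamma, beta and
gamma quantiles, chi-square tails) and root bracketing only.

Two-sided exact p-values follow the "sum of outcomes no more likely than the
observed one" convention; Monte-Carlo p-values are reported with +1 smoothing,
(k+1)/(n_sim+1).  No multiple-testing correction is applied anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp
from scipy.stats import beta as beta_dist
from scipy.stats import chi2 as chi2_dist
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm as norm_dist
from scipy.stats import poisson as poisson_dist

__all__ = [
    "Table2x2",
    "GWAExpectation",
    "fisher_exact",
    "fisher_or_bounds",
    "binom_exact_ci",
    "binom_exact_test",
    "wilcoxon_rank_sum",
    "multisample_proportion_test",
    "multinomial_omnibus",
]

# relative slack when comparing outcome probabilities for two-sided sums,
# guarding against ties broken by floating-point noise
_REL_EPS = 1e-7

#: switch from exact binomial arithmetic to the Poisson/gamma evaluation path
LARGE_N = 10**6


@dataclass(frozen=True)
class Table2x2:
    """A 2x2 contingency table; rows = groups, columns = outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("table entries must be non-negative")
        if self.total == 0:
            raise ValueError("table total must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_rows(cls, rows) -> "Table2x2":
        (a, b), (c, d) = rows
        return cls(a, b, c, d)


def _hypergeom_support(t: Table2x2) -> tuple[np.ndarray, np.ndarray]:
    """Support of the conditional distribution of cell ``a`` and log-weights
    log C(r1, k) + log C(r2, c1-k); the central pmf is weights / sum."""
    r1, r2 = t.a + t.b, t.c + t.d
    c1 = t.a + t.c
    lo, hi = max(0, c1 - r2), min(c1, r1)
    ks = np.arange(lo, hi + 1)
    logw = (
        gammaln(r1 + 1) - gammaln(ks + 1) - gammaln(r1 - ks + 1)
        + gammaln(r2 + 1) - gammaln(c1 - ks + 1) - gammaln(r2 - (c1 - ks) + 1)
    )
    return ks, logw


def fisher_exact(t: Table2x2, alternative: str = "two_sided") -> float:
    """Fisher's exact test on a 2x2 table.

    two_sided: sum of hypergeometric point probabilities <= the observed
    one; greater/less: upper/lower tail of cell ``a``.
    """
    if t.a + t.b == 0 or t.c + t.d == 0 or t.a + t.c == 0 or t.b + t.d == 0:
        return 1.0
    ks, logw = _hypergeom_support(t)
    logp = logw - logsumexp(logw)
    p_obs = logp[ks == t.a][0]
    if alternative == "two_sided":
        keep = logp <= p_obs + math.log1p(_REL_EPS)
    elif alternative == "greater":
        keep = ks >= t.a
    elif alternative == "less":
        keep = ks <= t.a
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(min(1.0, math.exp(logsumexp(logp[keep]))))


def _nc_tail(logw: np.ndarray, ks: np.ndarray, a: int, log_psi: float, upper: bool) -> float:
    """P(X >= a | psi) (or <=) under the noncentral hypergeometric law."""
    logterms = logw + ks * log_psi
    denom = logsumexp(logterms)
    mask = ks >= a if upper else ks <= a
    return math.exp(logsumexp(logterms[mask]) - denom)


def fisher_or_bounds(
    t: Table2x2, conf: float = 0.95, alternative: str = "two_sided"
) -> tuple[float, float]:
    """Exact confidence bounds for the conditional odds ratio.

    The bounds invert tail probabilities of the noncentral hypergeometric
    likelihood: for ``greater`` at confidence ``conf`` the lower bound solves
    P(X >= a | psi) = 1 - conf (upper bound infinity); ``two_sided`` puts
    (1-conf)/2 in each tail.  psi is found by bracketed root-finding on the
    log scale to relative tolerance 1e-6.
    """
    if not 0 < conf < 1:
        raise ValueError("conf must be in (0, 1)")
    if t.a + t.b == 0 or t.c + t.d == 0 or t.a + t.c == 0 or t.b + t.d == 0:
        return (0.0, math.inf)
    ks, logw = _hypergeom_support(t)
    alpha = 1 - conf
    tail = alpha / 2 if alternative == "two_sided" else alpha

    def solve(target_fn) -> float:
        f = lambda lp: target_fn(lp) - tail
        lo, hi = -1.0, 1.0
        while f(lo) * f(hi) > 0 and hi < 60:
            lo -= 3.0
            hi += 3.0
        lp = brentq(f, lo, hi, rtol=1e-9)
        return math.exp(lp)

    k_min, k_max = ks[0], ks[-1]
    lo_bound = 0.0
    hi_bound = math.inf
    if alternative in ("two_sided", "greater"):
        # lower bound: psi below which observing >= a becomes too surprising
        if t.a > k_min:
            lo_bound = solve(lambda lp: _nc_tail(logw, ks, t.a, lp, upper=True))
    if alternative in ("two_sided", "less"):
        if t.a < k_max:
            hi_bound = solve(lambda lp: _nc_tail(logw, ks, t.a, lp, upper=False))
    if alternative == "greater":
        hi_bound = math.inf
    if alternative == "less":
        lo_bound = 0.0
    return (lo_bound, hi_bound)


def binom_exact_ci(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact interval for a binomial proportion.

    For n > 10**6 (the regime of 1e8-genome exposures) the equivalent
    Poisson/gamma bounds are used: lo = qgamma(alpha/2, x)/n,
    hi = qgamma(1-alpha/2, x+1)/n, accurate to relative error < 1e-6 when
    the proportion is tiny.
    """
    n = int(round(n))
    if not 0 <= x <= n:
        raise ValueError("need 0 <= x <= n")
    if not 0 < conf < 1:
        raise ValueError("conf must be in (0, 1)")
    alpha = 1 - conf
    if n > LARGE_N:
        lo = 0.0 if x == 0 else float(gamma_dist.ppf(alpha / 2, x)) / n
        hi = float(gamma_dist.ppf(1 - alpha / 2, x + 1)) / n
        return lo, min(1.0, hi)
    lo = 0.0 if x == 0 else float(beta_dist.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(beta_dist.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


def _binom_logpmf(k, n: int, p0: float):
    k = np.asarray(k, dtype=float)
    return (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + k * math.log(p0) + (n - k) * math.log1p(-p0)
    )


def binom_exact_test(x: int, n: int, p0: float, two_sided: bool = True) -> float:
    """Exact binomial test of H0: success probability = p0.

    Two-sided p sums Binomial(n, p0) point probabilities no larger than the
    observed one.  Above n = 10**6 with a small mean the Poisson limit is
    used; the crossover outcome on the other side of the mean is located by
    bisection on the monotone flank of the pmf, so the sum stays exact to
    relative error < 1e-6 without enumerating the support.
    """
    n = int(round(n))
    if not 0 <= x <= n:
        raise ValueError("need 0 <= x <= n")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    mean = n * p0
    if n > LARGE_N and mean < 1e5:
        return _poisson_two_sided(x, mean) if two_sided else _poisson_one_sided(x, mean)
    if not two_sided:
        if x >= mean:
            # upper tail
            ks = np.arange(x, n + 1)
            return float(min(1.0, np.exp(logsumexp(_binom_logpmf(ks, n, p0)))))
        ks = np.arange(0, x + 1)
        return float(min(1.0, np.exp(logsumexp(_binom_logpmf(ks, n, p0)))))
    ks = np.arange(0, n + 1)
    logp = _binom_logpmf(ks, n, p0)
    p_obs = logp[x]
    keep = logp <= p_obs + math.log1p(_REL_EPS)
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def _poisson_one_sided(x: int, lam: float) -> float:
    if x >= lam:
        return float(poisson_dist.sf(x - 1, lam))
    return float(poisson_dist.cdf(x, lam))


def _poisson_crossover(x: int, lam: float) -> int | None:
    """Largest k on the far flank with pmf(k) <= pmf(x) (x above the mean),
    or smallest such k (x below the mean); None if no such outcome."""
    logp_obs = poisson_dist.logpmf(x, lam)
    mode = int(math.floor(lam))
    if x > lam:
        # search 0..mode for the largest k with logpmf <= logp_obs
        lo, hi = 0, mode
        if poisson_dist.logpmf(mode, lam) <= logp_obs + math.log1p(_REL_EPS):
            return mode
        if poisson_dist.logpmf(0, lam) > logp_obs + math.log1p(_REL_EPS):
            return None
        while hi - lo > 1:  # pmf increasing on [0, mode]
            mid = (lo + hi) // 2
            if poisson_dist.logpmf(mid, lam) <= logp_obs + math.log1p(_REL_EPS):
                lo = mid
            else:
                hi = mid
        return lo
    # x below the mean: smallest k >= mode with pmf <= pmf(x)
    lo, hi = mode, mode + max(10, int(20 * math.sqrt(lam) + 10))
    while poisson_dist.logpmf(hi, lam) > logp_obs + math.log1p(_REL_EPS):
        hi *= 2
    while hi - lo > 1:  # pmf decreasing on [mode, inf)
        mid = (lo + hi) // 2
        if poisson_dist.logpmf(mid, lam) <= logp_obs + math.log1p(_REL_EPS):
            hi = mid
        else:
            lo = mid
    return hi


def _poisson_two_sided(x: int, lam: float) -> float:
    if x >= lam:
        p = float(poisson_dist.sf(x - 1, lam))
        k = _poisson_crossover(x, lam)
        if k is not None:
            p += float(poisson_dist.cdf(k, lam))
    else:
        p = float(poisson_dist.cdf(x, lam))
        k = _poisson_crossover(x, lam)
        if k is not None:
            p += float(poisson_dist.sf(k - 1, lam))
    return min(1.0, p)


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sv = values[order]
    i = 0
    while i < len(sv):
        j = i
        while j + 1 < len(sv) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def wilcoxon_rank_sum(xs, ys, two_sided: bool = True) -> float:
    """Rank-sum (Mann-Whitney/Wilcoxon) test with midranks for ties.

    Exact permutation null (full enumeration of group assignments) for
    combined n <= 20; otherwise the normal approximation with tie
    correction.  The two-sided exact p counts assignments whose rank-sum
    deviates from its permutation mean by at least the observed deviation,
    which is symmetric under swapping the samples.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    n1, n2 = len(xs), len(ys)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([xs, ys])
    if np.all(pooled == pooled[0]):
        return 1.0
    ranks = _midranks(pooled)
    w_obs = ranks[:n1].sum()
    n = n1 + n2
    mu = n1 * (n + 1) / 2
    if n <= 20:
        from itertools import combinations

        dev_obs = abs(w_obs - mu)
        count = 0
        total = 0
        for idx in combinations(range(n), n1):
            w = ranks[list(idx)].sum()
            total += 1
            if two_sided:
                if abs(w - mu) >= dev_obs - 1e-12:
                    count += 1
            else:
                if w >= w_obs - 1e-12:
                    count += 1
        return count / total
    # normal approximation with tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return 1.0
    z = (w_obs - mu) / math.sqrt(var)
    if two_sided:
        return float(2 * norm_dist.sf(abs(z)))
    return float(norm_dist.sf(z))


def _prop_chi2_stat(x: np.ndarray, n: np.ndarray) -> float:
    p_hat = x.sum() / n.sum()
    if p_hat in (0.0, 1.0):
        return 0.0
    expected = n * p_hat
    return float(np.sum((x - expected) ** 2 / (expected * (1 - p_hat))))


def multisample_proportion_test(
    x, n, mode: str = "chi2", n_sim: int = 10**5, rng=None
) -> float:
    """Test of equal event proportions across k samples with exposures n.

    ``chi2``: the score (Pearson) statistic against the pooled proportion,
    df = k-1.  ``monte_carlo``: conditional on the total count, counts are
    multinomial over samples with probabilities proportional to exposures;
    the tail of the same statistic is estimated by simulation with +1
    smoothing -- preferred when expected counts are below ~5.
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    if len(x) != len(n) or len(x) < 2:
        raise ValueError("need matching counts/exposures for >= 2 samples")
    if np.any(n <= 0) or np.any(x < 0):
        raise ValueError("exposures must be positive, counts non-negative")
    if x.sum() == 0:
        return 1.0
    stat = _prop_chi2_stat(x, n)
    if mode == "chi2":
        return float(chi2_dist.sf(stat, len(x) - 1))
    if mode != "monte_carlo":
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(rng)
    total = int(round(x.sum()))
    probs = n / n.sum()
    sims = rng.multinomial(total, probs, size=n_sim).astype(float)
    expected = total * probs
    p_hat = total / n.sum()
    stats_sim = np.sum((sims - expected) ** 2 / (expected * (1 - p_hat)), axis=1)
    k = int(np.sum(stats_sim >= stat - 1e-12))
    return (k + 1) / (n_sim + 1)


@dataclass(frozen=True)
class GWAExpectation:
    """Expected per-generation rates per mutation type (externally supplied,
    e.g. genome-wide averages, optionally context-adjusted upstream)."""

    rates: dict

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.rates.values()):
            raise ValueError("expected rates must be positive")

    def renormalized(self, types) -> np.ndarray:
        """Probabilities over a chosen observable subset of types."""
        missing = [t for t in types if t not in self.rates]
        if missing:
            raise ValueError(f"expectation missing types: {missing}")
        v = np.array([self.rates[t] for t in types], dtype=float)
        return v / v.sum()


def multinomial_omnibus(
    observed: dict, expected: GWAExpectation, n_sim: int = 10**5, rng=None
) -> float:
    """Monte-Carlo omnibus test of an observed mutation-type spectrum
    against expected proportions (renormalized over the observed types,
    i.e. after artifact classes have been removed upstream).

    Statistic: multinomial log-likelihood ratio G = 2 * sum o_i log(o_i / e_i).
    """
    types = sorted(observed)
    counts = np.array([observed[t] for t in types], dtype=float)
    if counts.sum() <= 0:
        raise ValueError("observed spectrum is empty")
    probs = expected.renormalized(types)
    total = int(round(counts.sum()))

    def g_stat(c: np.ndarray) -> np.ndarray:
        e = total * probs
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(c > 0, c * np.log(c / e), 0.0)
        return 2 * terms.sum(axis=-1)

    stat = float(g_stat(counts))
    rng = np.random.default_rng(rng)
    sims = rng.multinomial(total, probs, size=n_sim).astype(float)
    e = total * probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(sims > 0, sims * np.log(sims / e), 0.0)
    stats_sim = 2 * terms.sum(axis=1)
    k = int(np.sum(stats_sim >= stat - 1e-12))
    return (k + 1) / (n_sim + 1)
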