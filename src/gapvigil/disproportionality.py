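"""Disproportionality analysis of spontaneous adverse-event reports.

Implements the four signal-detection statistics routinely applied to
spontaneous-report databases — the proportional reporting ratio (PRR), the
reporting odds ratio (ROR), the Bayesian information component (IC), and the
multi-item gamma-Poisson shrinker (MGPS) empirical-Bayes geometric mean
(EBGM) — together with their lower uncertainty bounds (PRR025, ROR025, IC025,
EB05) and the combined four-way signal rule

    IC025 > 0  and  PRR025 > 1  and  ROR025 > 1  and  EB05 > 1.

All statistics operate on report-level 2x2 contingency tables: for a drug D
and event E, n11 counts reports mentioning both, n10 drug-only, n01
event-only, n00 neither.  Repeated mentions within one report count once.

The IC follows the gamma-Poisson shrinkage formulation: with E the expected
co-report count under independence, IC = log2((n11 + 0.5)/(E + 0.5)), and
IC025 is the exact 2.5th percentile of log2(lambda) under the posterior
lambda*(E + 0.5) ~ Gamma(n11 + 0.5, 1).  The MGPS prior is DuMouchel's
two-component gamma mixture on the relative reporting rate lambda, fitted by
maximum marginal likelihood over all drug-event pairs of the database.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "ReportDatabase",
    "ContingencyTable",
    "MgpsPrior",
    "SignalStatistics",
    "SignalDecision",
    "build_contingency",
    "prr_with_bound",
    "ror_with_bound",
    "ic_with_bound",
    "fit_mgps_prior",
    "ebgm_with_bound",
    "screen_signals",
]

_Z975 = 1.959963984540054  # standard normal 97.5th percentile


@dataclass
class ReportDatabase:
    """A collection of spontaneous adverse-event reports.

    Each report is (report_id, age_group, drugs, events); drug and event sets
    are deduplicated and must be nonempty, report ids unique.
    """

    reports: list[tuple[str, str, frozenset, frozenset]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.reports]
        if len(ids) != len(set(ids)):
            raise ValueError("report ids must be unique")
        for rid, _age, drugs, events in self.reports:
            if not drugs or not events:
                raise ValueError(f"report {rid!r} must list >=1 drug and >=1 event")

    def __len__(self) -> int:
        return len(self.reports)

    @property
    def drugs(self) -> set:
        out: set = set()
        for _, _, d, _ in self.reports:
            out |= d
        return out

    @property
    def events(self) -> set:
        out: set = set()
        for _, _, _, e in self.reports:
            out |= e
        return out

    def subset_age(self, age_group: str) -> "ReportDatabase":
        """Restrict to one age stratum (e.g. '0-2y'), mirroring how a single
        pediatric stratum is analyzed by filtering rather than stratifying."""
        return ReportDatabase([r for r in self.reports if r[1] == age_group])


@dataclass(frozen=True)
class ContingencyTable:
    """Report-level 2x2 table for one drug-event pair."""

    n11: float
    n10: float
    n01: float
    n00: float

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("contingency cells must be nonnegative")
        if self.total <= 0:
            raise ValueError("contingency table must have N > 0")

    @property
    def total(self) -> float:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def expected(self) -> float:
        """Expected n11 under independence: row1 * col1 / N."""
        return (self.n11 + self.n10) * (self.n11 + self.n01) / self.total

    def corrected(self, delta: float = 0.5) -> "ContingencyTable":
        """Continuity-corrected copy (delta added to every cell)."""
        return ContingencyTable(
            self.n11 + delta, self.n10 + delta, self.n01 + delta, self.n00 + delta
        )


def build_contingency(db: ReportDatabase, drug, event) -> ContingencyTable:
    """Count reports into the 2x2 table for one drug-event pair.

    Each report falls in exactly one cell; absence of the drug or event from
    the whole database yields n11 = 0, not an error.
    """
    if len(db) == 0:
        raise ValueError("report database is empty")
    n11 = n10 = n01 = n00 = 0
    for _, _, drugs, events in db.reports:
        d = drug in drugs
        e = event in events
        if d and e:
            n11 += 1
        elif d:
            n10 += 1
        elif e:
            n01 += 1
        else:
            n00 += 1
    return ContingencyTable(n11, n10, n01, n00)


def contingency_tables(
    db: ReportDatabase, pairs: Sequence[tuple] | None = None
) -> dict[tuple, ContingencyTable]:
    """Vectorized 2x2 tables for many pairs (all drug x event pairs if None)."""
    if len(db) == 0:
        raise ValueError("report database is empty")
    drugs = sorted(db.drugs)
    events = sorted(db.events)
    di = {d: i for i, d in enumerate(drugs)}
    ei = {e: i for i, e in enumerate(events)}
    N = len(db)
    D = np.zeros((N, len(drugs)), dtype=bool)
    E = np.zeros((N, len(events)), dtype=bool)
    for r, (_, _, ds, es) in enumerate(db.reports):
        for d in ds:
            D[r, di[d]] = True
        for e in es:
            E[r, ei[e]] = True
    co = D.T.astype(np.int64) @ E.astype(np.int64)  # n11 for every pair
    drow = D.sum(axis=0)
    ecol = E.sum(axis=0)
    if pairs is None:
        pairs = [(d, e) for d in drugs for e in events]
    out = {}
    for d, e in pairs:
        n11 = int(co[di[d], ei[e]]) if d in di and e in ei else 0
        nd = int(drow[di[d]]) if d in di else 0
        ne = int(ecol[ei[e]]) if e in ei else 0
        out[(d, e)] = ContingencyTable(n11, nd - n11, ne - n11, N - nd - ne + n11)
    return out


def prr_with_bound(
    t: ContingencyTable, continuity_correction: bool = False
) -> tuple[float, float]:
    """Proportional reporting ratio and its 95% lower limit.

    PRR = [n11/(n11+n10)] / [n01/(n01+n00)]; the interval is computed on the
    log scale with standard error
    sqrt(1/n11 - 1/(n11+n10) + 1/n01 - 1/(n01+n00)).
    With a zero n11 or n01 the bound is undefined (nan) unless the
    continuity-correction flag adds 0.5 to every cell.
    """
    if continuity_correction:
        t = t.corrected()
    if t.n11 + t.n10 <= 0 or t.n11 + t.n01 <= 0:
        raise ValueError("PRR requires positive drug and event margins")
    if t.n01 + t.n00 <= 0:
        return math.nan, math.nan
    if t.n11 == 0 or t.n01 == 0:
        prr = 0.0 if t.n11 == 0 and t.n01 > 0 else math.inf
        return prr, math.nan
    prr = (t.n11 / (t.n11 + t.n10)) / (t.n01 / (t.n01 + t.n00))
    se = math.sqrt(
        1.0 / t.n11 - 1.0 / (t.n11 + t.n10) + 1.0 / t.n01 - 1.0 / (t.n01 + t.n00)
    )
    return prr, math.exp(math.log(prr) - _Z975 * se)


def ror_with_bound(
    t: ContingencyTable, continuity_correction: bool = False
) -> tuple[float, float]:
    """Reporting odds ratio (n11*n00)/(n10*n01) and its 95% lower limit."""
    if continuity_correction:
        t = t.corrected()
    if t.n10 == 0 or t.n01 == 0:
        return math.inf if t.n11 > 0 else math.nan, math.nan
    if t.n11 == 0 or t.n00 == 0:
        ror = 0.0 if t.n11 == 0 else math.inf
        return ror, math.nan
    ror = (t.n11 * t.n00) / (t.n10 * t.n01)
    se = math.sqrt(1.0 / t.n11 + 1.0 / t.n10 + 1.0 / t.n01 + 1.0 / t.n00)
    return ror, math.exp(math.log(ror) - _Z975 * se)


def ic_with_bound(t: ContingencyTable) -> tuple[float, float]:
    """Shrunk information component and exact 2.5th-percentile lower bound.

    IC = log2((n11 + 0.5)/(E + 0.5)).  Under the gamma posterior
    lambda*(E + 0.5) ~ Gamma(n11 + 0.5, 1), IC025 is the exact 0.025 quantile
    of log2(lambda).  The 0.5 offsets keep both finite for any table.
    """
    e = t.expected
    ic = math.log2((t.n11 + 0.5) / (e + 0.5))
    q = stats.gamma.ppf(0.025, a=t.n11 + 0.5)  # scale 1
    ic025 = math.log2(q / (e + 0.5))
    return ic, ic025


# ---------------------------------------------------------------------------
# MGPS (DuMouchel two-component gamma mixture empirical Bayes)
# ---------------------------------------------------------------------------

#: canonical optimizer start point (alpha1, beta1, alpha2, beta2, mix_p)
MGPS_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


@dataclass(frozen=True)
class MgpsPrior:
    """Two-component gamma mixture prior on the relative reporting rate.

    lambda ~ mix_p * Gamma(alpha1, rate=beta1) + (1-mix_p) * Gamma(alpha2, rate=beta2)
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    mix_p: float
    loglik: float = math.nan
    converged: bool = True

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma shapes and rates must be positive")
        if not 0.0 <= self.mix_p <= 1.0:
            raise ValueError("mix_p must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return self.mix_p * self.alpha1 / self.beta1 + (1 - self.mix_p) * self.alpha2 / self.beta2

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.alpha1, self.beta1, self.alpha2, self.beta2, self.mix_p)


class MgpsConvergenceError(RuntimeError):
    """Raised when the marginal-likelihood fit fails; carries best-so-far."""

    def __init__(self, message: str, best: MgpsPrior):
        super().__init__(message)
        self.best = best


#: box for the unconstrained parameters (log shapes/rates, logit weight);
#: wide enough for any plausible prior, tight enough to keep exp/expit finite
_THETA_BOUND = 15.0


def _mixture_nll(theta: np.ndarray, n: np.ndarray, e: np.ndarray) -> float:
    """Negative marginal log-likelihood; theta = log params + logit mix."""
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        a1, b1, a2, b2 = np.exp(theta[:4])
        p = special.expit(theta[4])
        # marginal of Poisson(lambda*E) with Gamma(a, rate=b) on lambda is
        # NegBin(size=a, prob=b/(b+E))
        l1 = stats.nbinom.logpmf(n, a1, b1 / (b1 + e))
        l2 = stats.nbinom.logpmf(n, a2, b2 / (b2 + e))
        ll = special.logsumexp(
            np.stack([l1 + np.log(p), l2 + np.log1p(-p)]), axis=0
        )
    out = -float(np.sum(ll))
    return out if math.isfinite(out) else 1e300


def fit_mgps_prior(
    tables: Iterable[ContingencyTable] | dict,
    start: Sequence[float] = MGPS_START,
    max_iter: int = 500,
) -> MgpsPrior:
    """Fit the two-component gamma mixture by maximum marginal likelihood.

    ``tables`` is every drug-event 2x2 table of the database (or the dict from
    :func:`contingency_tables`).  The five parameters are optimized on an
    unconstrained scale (log shapes/rates, logit weight) with L-BFGS-B from
    the documented start point.  Non-convergence raises
    :class:`MgpsConvergenceError` carrying the best iterate.
    """
    if isinstance(tables, dict):
        tables = list(tables.values())
    else:
        tables = list(tables)
    if len(tables) < 2:
        raise ValueError("MGPS fit needs >=2 drug-event pairs")
    n = np.array([t.n11 for t in tables], dtype=float)
    e = np.array([t.expected for t in tables], dtype=float)
    return fit_mgps_prior_counts(n, e, start=start, max_iter=max_iter)


def fit_mgps_prior_counts(
    n: np.ndarray,
    e: np.ndarray,
    start: Sequence[float] = MGPS_START,
    max_iter: int = 500,
) -> MgpsPrior:
    """Fit the MGPS prior from raw (observed count, expected count) pairs."""
    n = np.asarray(n, dtype=float)
    e = np.asarray(e, dtype=float)
    if n.size < 2 or n.size != e.size:
        raise ValueError("need >=2 aligned (n, E) pairs")
    if np.any(e <= 0):
        raise ValueError("all pairs must have expected count E > 0")
    x0 = np.array(
        [math.log(start[0]), math.log(start[1]), math.log(start[2]),
         math.log(start[3]), special.logit(start[4])]
    )
    bounds = [(-_THETA_BOUND, _THETA_BOUND)] * 5
    res = optimize.minimize(
        _mixture_nll, x0, args=(n, e), method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iter},
    )
    converged = bool(res.success)
    if not converged:
        # derivative-free polish rescues occasional line-search failures;
        # a negligible relative gain means the objective has plateaued
        # (e.g. a boundary optimum with one component degenerating to a
        # point mass), which counts as converged
        polish = optimize.minimize(
            _mixture_nll, res.x, args=(n, e), method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-7, "fatol": 1e-9},
        )
        rel_gain = (res.fun - polish.fun) / (1.0 + abs(polish.fun))
        if polish.fun <= res.fun:
            res = polish
        converged = bool(polish.success) or rel_gain < 1e-3
    a1, b1, a2, b2 = np.exp(res.x[:4])
    p = float(special.expit(res.x[4]))
    # report the low-mean component first for a canonical ordering
    if a1 / b1 > a2 / b2:
        a1, b1, a2, b2, p = a2, b2, a1, b1, 1.0 - p
    prior = MgpsPrior(float(a1), float(b1), float(a2), float(b2), p,
                      loglik=-float(res.fun), converged=converged)
    if not converged:
        raise MgpsConvergenceError(f"MGPS fit did not converge: {res.message}", prior)
    return prior


def _posterior_mixture(t: ContingencyTable, prior: MgpsPrior):
    """Posterior of lambda given n11: gamma mixture with updated weights."""
    n, e = t.n11, t.expected
    a = np.array([prior.alpha1 + n, prior.alpha2 + n])
    b = np.array([prior.beta1 + e, prior.beta2 + e])
    logw = np.array([
        math.log(prior.mix_p) if prior.mix_p > 0 else -math.inf,
        math.log1p(-prior.mix_p) if prior.mix_p < 1 else -math.inf,
    ])
    logw = logw + np.array([
        stats.nbinom.logpmf(n, prior.alpha1, prior.beta1 / (prior.beta1 + e)),
        stats.nbinom.logpmf(n, prior.alpha2, prior.beta2 / (prior.beta2 + e)),
    ])
    w = np.exp(logw - special.logsumexp(logw))
    return a, b, w


def ebgm_with_bound(t: ContingencyTable, prior: MgpsPrior) -> tuple[float, float]:
    """Empirical-Bayes geometric mean and 5th-percentile lower bound.

    The posterior of lambda is a two-component gamma mixture; EBGM is
    2**E[log2 lambda | data] from the exact digamma expression, and EB05 is
    the 5th percentile of the mixture found by root-finding on its CDF.
    """
    if t.expected <= 0:
        raise ValueError("EBGM requires expected count E > 0")
    a, b, w = _posterior_mixture(t, prior)
    mean_log = float(np.sum(w * (special.digamma(a) - np.log(b))))
    ebgm = math.exp(mean_log)  # 2**(E[log2 l]) == exp(E[ln l])

    def cdf(x: float) -> float:
        return float(np.sum(w * stats.gamma.cdf(x, a=a, scale=1.0 / b)))

    lo = min(float(stats.gamma.ppf(0.05, a=ai, scale=1.0 / bi)) for ai, bi in zip(a, b))
    hi = max(float(stats.gamma.ppf(0.05, a=ai, scale=1.0 / bi)) for ai, bi in zip(a, b))
    if hi <= lo:
        hi = lo + 1e-12
    eb05 = float(optimize.brentq(lambda x: cdf(x) - 0.05, lo * (1 - 1e-9),
                                 hi * (1 + 1e-9), xtol=1e-8, rtol=1e-10))
    return ebgm, eb05


@dataclass(frozen=True)
class SignalStatistics:
    prr: float
    prr025: float
    ror: float
    ror025: float
    ic: float
    ic025: float
    ebgm: float
    eb05: float


@dataclass(frozen=True)
class SignalDecision:
    drug: object
    event: object
    stats: SignalStatistics
    is_signal: bool
    reason: str | None = None  # set when a statistic is undefined


def _decide(s: SignalStatistics) -> tuple[bool, str | None]:
    vals = (s.prr025, s.ror025, s.ic025, s.eb05)
    if any(math.isnan(v) for v in vals):
        return False, "undefined_statistic"
    ok = s.ic025 > 0 and s.prr025 > 1 and s.ror025 > 1 and s.eb05 > 1
    return ok, None


def screen_signals(
    db: ReportDatabase,
    pairs: Sequence[tuple] | None = None,
    continuity_correction: bool = False,
    prior: MgpsPrior | None = None,
) -> list[SignalDecision]:
    """Run the four-way disproportionality screen on drug-event pairs.

    The MGPS prior is fitted once on all drug x event tables of the database
    (unless one is supplied); each pair is then a signal iff all four lower
    bounds clear their strict thresholds.  Pairs with an undefined statistic
    are non-signals with reason ``undefined_statistic``.
    """
    all_tables = contingency_tables(db)
    if prior is None:
        prior = fit_mgps_prior(all_tables)
    if pairs is None:
        pairs = sorted(all_tables)
    decisions = []
    for pair in pairs:
        t = all_tables.get(tuple(pair))
        if t is None:
            t = build_contingency(db, pair[0], pair[1])
        try:
            prr, prr025 = prr_with_bound(t, continuity_correction)
        except ValueError:
            prr = prr025 = math.nan
        ror, ror025 = ror_with_bound(t, continuity_correction)
        ic, ic025 = ic_with_bound(t)
        ebgm, eb05 = ebgm_with_bound(t, prior)
        s = SignalStatistics(prr, prr025, ror, ror025, ic, ic025, ebgm, eb05)
        ok, reason = _decide(s)
        decisions.append(SignalDecision(pair[0], pair[1], s, ok, reason))
    return decisions
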