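"""Single-hit Poisson limiting-dilution analysis.

A limiting-dilution transplantation assay doses recipients with d
cells and records whether each develops disease (or engrafts).  Under
the single-hit model an active cell initiates disease independently,
so P(no response | dose d) = exp(-f * d) where f is the active-cell
frequency; assays report 1/f ("one stem cell per x cells").  The
frequency is estimated by maximizing the binomial log-likelihood over
log f; 95% confidence limits come from the profile likelihood
(chi-square(1) drop), and two groups are compared with a 1-df
likelihood-ratio test against the pooled fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .io import DoseGroup

__all__ = [
    "DoseGroup",
    "FrequencyEstimate",
    "LDAComparison",
    "log_likelihood",
    "fit_single_hit",
    "compare_frequencies",
    "simulate_lda",
]

LOG_F_MIN = np.log(1e-9)
LOG_F_MAX = 0.0  # f <= 1: at most one active cell per transplanted cell
_XTOL = 1e-10


@dataclass
class FrequencyEstimate:
    """Active-cell frequency estimate with profile-likelihood CI."""

    f_hat: float
    ci_low: float
    ci_high: float
    loglik: float
    flag: str | None = None  # 'all_responded' | 'none_responded'

    @property
    def one_in(self) -> float:
        """Frequency expressed as 1/x cells."""
        return 1.0 / self.f_hat if self.f_hat > 0 else np.inf


@dataclass(frozen=True)
class LDAComparison:
    lr_statistic: float
    df: int
    p: float


def log_likelihood(log_f: float, groups: Sequence[DoseGroup]) -> float:
    """Binomial log-likelihood of the single-hit model at log f."""
    f = np.exp(log_f)
    ll = 0.0
    for g in groups:
        q = -f * g.dose  # log P(no response)
        k, n = g.n_responded, g.n_tested
        if k > 0:
            # log(1 - exp(-fd)) computed stably
            ll += k * np.log(-np.expm1(q))
        if n - k > 0:
            ll += (n - k) * q
    return float(ll)


def _check_groups(groups: Sequence[DoseGroup]) -> str | None:
    if not groups:
        raise ValueError("no dose groups")
    if all(g.n_responded == g.n_tested for g in groups):
        return "all_responded"
    if all(g.n_responded == 0 for g in groups):
        return "none_responded"
    return None


def _score(log_f: float, groups: Sequence[DoseGroup]) -> float:
    """d loglik / d log f (stable near q = 0)."""
    f = np.exp(log_f)
    tot = 0.0
    for g in groups:
        q = f * g.dose
        k, n = g.n_responded, g.n_tested
        if k > 0:
            tot += k * q * np.exp(-q) / (-np.expm1(-q))
        tot -= (n - k) * q
    return float(tot)


def _mle_log_f(groups: Sequence[DoseGroup]) -> float:
    res = optimize.minimize_scalar(
        lambda lf: -log_likelihood(lf, groups),
        bounds=(LOG_F_MIN, LOG_F_MAX),
        method="bounded",
        options={"xatol": _XTOL},
    )
    x = float(res.x)
    # polish with the score equation (bounded search stalls near sqrt(eps))
    a, b = max(x - 1e-3, LOG_F_MIN), min(x + 1e-3, LOG_F_MAX)
    sa, sb = _score(a, groups), _score(b, groups)
    if sa > 0 > sb:
        return float(optimize.brentq(_score, a, b, args=(groups,), xtol=1e-13))
    return x


def _profile_bound(
    groups: Sequence[DoseGroup], lf_hat: float, ll_target: float, side: str
) -> float:
    """Bisection for the log-f where the profile drops to ll_target."""
    lo, hi = (LOG_F_MIN, lf_hat) if side == "low" else (lf_hat, LOG_F_MAX)
    edge = lo if side == "low" else hi
    if log_likelihood(edge, groups) >= ll_target:
        return edge  # CI reaches the parameter bound
    def h(lf: float) -> float:
        return log_likelihood(lf, groups) - ll_target
    a, b = (edge, lf_hat) if side == "low" else (lf_hat, edge)
    return float(optimize.brentq(h, a, b, xtol=_XTOL))


def fit_single_hit(
    groups: Sequence[DoseGroup], confidence: float = 0.95
) -> FrequencyEstimate:
    """Maximum-likelihood frequency with a profile-likelihood CI.

    Degenerate tables are flagged rather than rejected: when every
    recipient responds the frequency is only bounded below (f_hat and
    ci_high pinned at 1); when none responds it is only bounded above
    (f_hat and ci_low pinned at 0).
    """
    flag = _check_groups(groups)
    drop = stats.chi2.ppf(confidence, df=1) / 2.0
    if flag == "all_responded":
        ll = log_likelihood(LOG_F_MAX, groups)  # == 0 at the boundary
        lo = _profile_bound(groups, LOG_F_MAX, ll - drop, "low")
        return FrequencyEstimate(1.0, float(np.exp(lo)), 1.0, ll, flag)
    if flag == "none_responded":
        ll = log_likelihood(LOG_F_MIN, groups)
        hi = _profile_bound(groups, LOG_F_MIN, ll - drop, "high")
        return FrequencyEstimate(0.0, 0.0, float(np.exp(hi)), ll, flag)
    lf_hat = _mle_log_f(groups)
    ll_hat = log_likelihood(lf_hat, groups)
    lo = _profile_bound(groups, lf_hat, ll_hat - drop, "low")
    hi = _profile_bound(groups, lf_hat, ll_hat - drop, "high")
    return FrequencyEstimate(
        float(np.exp(lf_hat)), float(np.exp(lo)), float(np.exp(hi)), ll_hat
    )


def compare_frequencies(
    group_a: Sequence[DoseGroup], group_b: Sequence[DoseGroup]
) -> LDAComparison:
    """1-df likelihood-ratio test of equal frequencies in two groups."""
    import warnings

    fa = fit_single_hit(group_a)
    fb = fit_single_hit(group_b)
    if fa.flag or fb.flag:
        warnings.warn("degenerate dose table(s); LR test is unreliable", stacklevel=2)
    ll_a = fa.loglik
    ll_b = fb.loglik
    pooled = list(group_a) + list(group_b)
    flag_p = _check_groups(pooled)
    lf_pool = (
        LOG_F_MAX if flag_p == "all_responded" else LOG_F_MIN if flag_p == "none_responded" else _mle_log_f(pooled)
    )
    ll_pool = log_likelihood(lf_pool, pooled)
    lr = max(2.0 * (ll_a + ll_b - ll_pool), 0.0)
    p = float(stats.chi2.sf(lr, df=1)) if lr > 0 else 1.0
    return LDAComparison(lr, 1, p)


def simulate_lda(
    f: float,
    doses: Sequence[float],
    n_per_dose: int | Sequence[int],
    seed: int | np.random.Generator,
) -> list[DoseGroup]:
    """Draw a single-hit dose-response table: responders per dose are
    Binomial(n, 1 - exp(-f d))."""
    if not 0 <= f <= 1:
        raise ValueError("f must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if np.isscalar(n_per_dose):
        n_per_dose = [int(n_per_dose)] * len(doses)
    out = []
    for d, n in zip(doses, n_per_dose):
        p_resp = -np.expm1(-f * d)
        out.append(DoseGroup(float(d), int(n), int(rng.binomial(n, p_resp))))
    return out
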