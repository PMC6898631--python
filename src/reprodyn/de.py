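"""Normalization and time-course differential testing.

The statistical core is a negative-binomial (NB) Wald test of each
time point against the 0 h baseline of the same condition, on counts
normalized by median-of-ratios size factors.  On top of the ordinary
q < alpha call sits a replicate-level noise filter: for each gene and
time point the fold change under induction is divided by the fold
change in the parallel uninduced culture, giving per-replicate-pair
ratios r_i.  A t-interval on mean log2 r that excludes 1 marks the
gene as genuinely induction-affected; shared culture drift cancels in
r and is filtered out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, SampleSheet

__all__ = [
    "SizeFactors",
    "RatioRecord",
    "estimate_size_factors",
    "reference_size_factors",
    "bh_adjust",
    "test_differential",
    "fold_change_ratio",
    "fold_change_ratios",
    "ratio_ci",
    "ratio_ci_filter",
    "osk_affected_genes",
]

DISPERSION_FLOOR = 1e-8
FC_PSEUDOCOUNT = 0.5


@dataclass
class RatioRecord:
    """Per (feature, time) dox-vs-control fold-change ratios with CI."""

    feature_id: str
    time_h: float
    r_values: np.ndarray
    ci_low: float = np.nan
    ci_high: float = np.nan
    osk_affected: bool = False


class SizeFactors:
    """Per-sample positive multipliers with geometric mean 1."""

    def __init__(self, sample_ids: list[str], factors: np.ndarray):
        factors = np.asarray(factors, dtype=float)
        if (factors <= 0).any():
            raise ValueError("size factors must be positive")
        if len(sample_ids) != factors.size:
            raise ValueError("one factor per sample required")
        self.sample_ids = list(sample_ids)
        self.factors = factors

    def __getitem__(self, sample_id: str) -> float:
        return float(self.factors[self.sample_ids.index(sample_id)])

    def aligned_to(self, sample_ids: list[str]) -> np.ndarray:
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return self.factors[idx]


def estimate_size_factors(cm: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the per-feature geometric mean across samples,
    using only features positive in every sample; each sample's factor
    is the median of count/reference over those features.
    """
    counts = cm.counts.astype(float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("no feature with nonzero counts in every sample")
    sub = counts[all_positive]
    ref = np.exp(np.mean(np.log(sub), axis=1))
    factors = np.median(sub / ref[:, None], axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return SizeFactors(cm.sample_ids, factors)


def reference_size_factors(
    cm: CountMatrix,
    sheet: SampleSheet,
    condition: str,
    alpha: float = 0.05,
    min_reference_frac: float = 0.2,
) -> SizeFactors:
    """Two-pass median-of-ratios size factors robust to one-sided change.

    When a large fraction of features moves in one direction (a global
    chromatin opening, say), the median ratio is percentile-shifted and
    every null feature inherits a spurious fold change.  This estimator
    runs the differential test once with plain size factors, removes
    the features called significant at any time point, and re-estimates
    the factors on the remaining (presumed null) reference set.  With
    fewer than ``min_reference_frac`` features left, the first-pass
    factors are returned unchanged.
    """
    sf = estimate_size_factors(cm)
    changed: set[str] = set()
    for t in sheet.times:
        if t == 0:
            continue
        res = test_differential(cm, sheet, sf, condition, t, alpha)
        changed |= set(res.loc[res["significant"], "feature_id"])
    keep = [i for i, f in enumerate(cm.feature_ids) if f not in changed]
    if len(keep) < min_reference_frac * cm.n_features:
        return sf
    sub = CountMatrix(
        [cm.feature_ids[i] for i in keep], cm.sample_ids, cm.counts[keep, :]
    )
    positive = (sub.counts > 0).all(axis=1)
    if not positive.any():
        return sf
    return estimate_size_factors(sub)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _stratum_counts(
    cm: CountMatrix, sheet: SampleSheet, sf: SizeFactors, condition: str, time_h: float
) -> np.ndarray:
    """Normalized counts (features x replicates) for one stratum."""
    rows = sheet.samples_at(condition, time_h)
    if len(rows) == 0:
        raise ValueError(f"no samples in stratum ({condition}, {time_h} h)")
    ids = list(rows["sample_id"])
    idx = [cm.sample_ids.index(s) for s in ids]
    return cm.counts[:, idx] / sf.aligned_to(ids)[None, :]


def _fit_dispersion_trend(mu: np.ndarray, alpha_mom: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu on positive method-of-moments estimates
    (nonnegative least squares); returns the trend evaluated at mu."""
    ok = (mu > 0) & (alpha_mom > 0) & np.isfinite(alpha_mom)
    if ok.sum() < 3:
        fallback = float(np.mean(alpha_mom[ok])) if ok.any() else DISPERSION_FLOOR
        return np.full_like(mu, max(fallback, DISPERSION_FLOOR))
    design = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, _ = optimize.nnls(design, alpha_mom[ok])
    with np.errstate(divide="ignore"):
        trend = coef[0] + coef[1] / np.where(mu > 0, mu, np.inf)
    return np.maximum(trend, DISPERSION_FLOOR)


def test_differential(
    cm: CountMatrix,
    sheet: SampleSheet,
    sf: SizeFactors,
    condition: str,
    time_h: float,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """NB Wald test of time ``time_h`` against 0 h within one condition.

    Per-feature dispersion is a method-of-moments estimate from the two
    strata, floored at 1e-8 and shrunk 50/50 toward a fitted
    ``a0 + a1/mu`` mean-dispersion trend.  Features with zero counts
    throughout get a NaN log2fc sentinel and p = 1.

    Returns a DataFrame with feature, log2fc, p, q, significant.
    """
    if time_h == 0:
        raise ValueError("time must differ from the 0 h baseline")
    y_t = _stratum_counts(cm, sheet, sf, condition, time_h)
    y_0 = _stratum_counts(cm, sheet, sf, condition, 0.0)
    n_t, n_0 = y_t.shape[1], y_0.shape[1]
    if n_t < 2 or n_0 < 2:
        raise ValueError("need >= 2 replicates in both strata")

    mu_t = y_t.mean(axis=1)
    mu_0 = y_0.mean(axis=1)
    mu_bar = (mu_t + mu_0) / 2.0
    # pooled within-stratum variance of normalized counts
    ss = ((y_t - mu_t[:, None]) ** 2).sum(axis=1) + ((y_0 - mu_0[:, None]) ** 2).sum(axis=1)
    s2 = ss / (n_t + n_0 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = np.where(mu_bar > 0, (s2 - mu_bar) / mu_bar**2, 0.0)
    trend = _fit_dispersion_trend(mu_bar, alpha_mom)
    disp = np.maximum(0.5 * np.maximum(alpha_mom, 0.0) + 0.5 * trend, DISPERSION_FLOOR)

    c = FC_PSEUDOCOUNT
    log2fc = np.log2((mu_t + c) / (mu_0 + c))
    # delta-method variance of log2 of an NB stratum mean
    ln2sq = np.log(2.0) ** 2
    var = (1.0 / (mu_t + c) + disp) / (n_t * ln2sq) + (1.0 / (mu_0 + c) + disp) / (n_0 * ln2sq)
    z = np.where(var > 0, log2fc / np.sqrt(var), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.minimum(p, 1.0)

    all_zero = (y_t.sum(axis=1) == 0) & (y_0.sum(axis=1) == 0)
    log2fc = np.where(all_zero, np.nan, log2fc)
    p = np.where(all_zero, 1.0, p)

    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "feature_id": cm.feature_ids,
            "condition": condition,
            "time_h": time_h,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "significant": q < alpha,
        }
    )


def fold_change_ratios(
    cm: CountMatrix,
    sheet: SampleSheet,
    sf: SizeFactors,
    time_h: float,
    pairing: str = "index",
    pseudocount: float = FC_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-feature dox/control fold-change ratios at one time point.

    For replicate pair i, FC = (normalized count at t + c)/(normalized
    count at 0 + c) within each arm and r_i = FC_dox,i / FC_ctrl,i.
    ``pairing`` is "index" (dox replicate i with control replicate i)
    or "all" (every dox x control pair).

    Returns a DataFrame with one row per feature and one ``r{i}``
    column per pair.
    """
    if pairing not in ("index", "all"):
        raise ValueError(f"unknown pairing {pairing!r}")
    arms = {}
    for cond in ("dox", "control"):
        y_t = _stratum_counts(cm, sheet, sf, cond, time_h)
        y_0 = _stratum_counts(cm, sheet, sf, cond, 0.0)
        if y_t.shape[1] < 2 or y_0.shape[1] < 2:
            raise ValueError(f"{cond} arm needs >= 2 replicates at t and 0")
        reps_t = list(sheet.samples_at(cond, time_h)["replicate"])
        reps_0 = list(sheet.samples_at(cond, 0.0)["replicate"])
        arms[cond] = (y_t, y_0, reps_t, reps_0)

    c = pseudocount

    def arm_fc(cond: str) -> dict[int, np.ndarray]:
        y_t, y_0, reps_t, reps_0 = arms[cond]
        fcs = {}
        for j, rep in enumerate(reps_t):
            if rep not in reps_0:
                raise ValueError(f"{cond} replicate {rep} missing at 0 h")
            k = reps_0.index(rep)
            fcs[rep] = (y_t[:, j] + c) / (y_0[:, k] + c)
        return fcs

    fc_dox = arm_fc("dox")
    fc_ctl = arm_fc("control")
    if pairing == "index":
        common = sorted(set(fc_dox) & set(fc_ctl))
        if set(fc_dox) != set(fc_ctl):
            raise ValueError(
                f"unmatched replicate indices: dox {sorted(fc_dox)} vs control {sorted(fc_ctl)}"
            )
        pairs = [(i, i) for i in common]
    else:
        pairs = [(i, j) for i in sorted(fc_dox) for j in sorted(fc_ctl)]
    r = np.column_stack([fc_dox[i] / fc_ctl[j] for i, j in pairs])
    out = pd.DataFrame(r, columns=[f"r{k + 1}" for k in range(r.shape[1])])
    out.insert(0, "feature_id", cm.feature_ids)
    out.insert(1, "time_h", time_h)
    return out


def fold_change_ratio(
    cm: CountMatrix,
    sheet: SampleSheet,
    sf: SizeFactors,
    feature_id: str,
    time_h: float,
    pairing: str = "index",
) -> RatioRecord:
    """Fold-change ratios for a single feature (see fold_change_ratios)."""
    table = fold_change_ratios(cm, sheet, sf, time_h, pairing)
    row = table[table["feature_id"] == feature_id]
    if row.empty:
        raise KeyError(f"unknown feature {feature_id!r}")
    r = row.iloc[0].drop(["feature_id", "time_h"]).to_numpy(dtype=float)
    return RatioRecord(feature_id, time_h, r)


def ratio_ci(r_values: np.ndarray, confidence: float = 0.95) -> tuple[float, float, bool]:
    """t-interval on mean log2(r), exponentiated back to the ratio scale.

    With zero variance the interval degenerates to the point {r}.  The
    gene is flagged as induction-affected when the interval excludes 1.
    """
    r = np.asarray(r_values, dtype=float)
    if r.size < 2:
        raise ValueError("need >= 2 replicate ratios")
    if (r <= 0).any() or not np.all(np.isfinite(r)):
        raise ValueError("ratios must be positive and finite")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    logr = np.log2(r)
    m = logr.mean()
    sd = logr.std(ddof=1)
    tq = stats.t.ppf(0.5 + confidence / 2.0, df=r.size - 1)
    half = tq * sd / np.sqrt(r.size)
    lo, hi = 2.0 ** (m - half), 2.0 ** (m + half)
    flagged = lo > 1.0 or hi < 1.0
    return float(lo), float(hi), bool(flagged)


def ratio_ci_filter(record: RatioRecord, confidence: float = 0.95) -> RatioRecord:
    """Attach the confidence interval and affected flag to a RatioRecord."""
    lo, hi, flagged = ratio_ci(record.r_values, confidence)
    return RatioRecord(record.feature_id, record.time_h, record.r_values, lo, hi, flagged)


def ratio_ci_table(ratios: pd.DataFrame, confidence: float = 0.95) -> pd.DataFrame:
    """Vectorized CI filter over a fold_change_ratios table."""
    rcols = [c for c in ratios.columns if c.startswith("r")]
    r = ratios[rcols].to_numpy(dtype=float)
    n = r.shape[1]
    if n < 2:
        raise ValueError("need >= 2 replicate ratios")
    if (r <= 0).any():
        raise ValueError("ratios must be positive")
    logr = np.log2(r)
    m = logr.mean(axis=1)
    sd = logr.std(axis=1, ddof=1)
    tq = stats.t.ppf(0.5 + confidence / 2.0, df=n - 1)
    half = tq * sd / np.sqrt(n)
    lo, hi = 2.0 ** (m - half), 2.0 ** (m + half)
    out = ratios.copy()
    out["ci_low"] = lo
    out["ci_high"] = hi
    out["osk_affected"] = (lo > 1.0) | (hi < 1.0)
    return out


def osk_affected_genes(
    de_table: pd.DataFrame, ratio_table: pd.DataFrame, alpha: float = 0.05
) -> list[str]:
    """Genes both DE-significant (q < alpha vs 0 h under dox) and flagged
    by the ratio-CI filter, at one time point."""
    de_feats = set(de_table["feature_id"])
    ratio_feats = set(ratio_table["feature_id"])
    if de_feats != ratio_feats:
        raise ValueError("DE and ratio tables cover different feature universes")
    sig = set(de_table.loc[de_table["q"] < alpha, "feature_id"])
    flagged = set(ratio_table.loc[ratio_table["osk_affected"], "feature_id"])
    return sorted(sig & flagged)
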