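"""Count statistics: normalization, NB differential expression, report metrics.

The differential-expression test follows the classic two-condition
negative-binomial exact test: library sizes are estimated by median-of-ratios,
per-feature dispersions by method-of-moments floored at a parametric
mean-dispersion trend, and the p-value is the two-sided exact tail over all
splits of the per-condition count sums.  Benjamini-Hochberg controls FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln


@dataclass
class CountMatrix:
    """Features x samples raw counts with a sample -> condition design.

    ``counts`` is a DataFrame (rows = feature ids, columns = sample ids);
    ``design`` maps each sample id to its condition label.
    """

    counts: pd.DataFrame
    design: dict[str, str]

    def __post_init__(self):
        missing = [s for s in self.counts.columns if s not in self.design]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.design[s] == condition]

    def subset(self, feature_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[feature_ids], dict(self.design))


@dataclass
class DEResult:
    feature_id: str
    mean_a: float
    mean_b: float
    log2fc: float
    p_value: float
    fdr: float = np.nan
    all_zero: bool = False


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding as used in printed report tables."""
    x = float(x)
    if not np.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Normalization

def size_factors(cm: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    For each feature with positive counts in every sample, compute the ratio
    of each sample's count to the feature's geometric mean across samples;
    the sample's factor is the median of those ratios.
    """
    counts = cm.counts if isinstance(cm, CountMatrix) else cm
    k = counts.to_numpy(dtype=float)
    positive = (k > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has positive counts in all samples; supply a "
            "pseudo-reference or filter samples"
        )
    logk = np.log(k[positive])
    log_geo_mean = logk.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logk - log_geo_mean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def tpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Tags-per-million per library: k_ij / column_total * 1e6."""
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        zero = list(totals.index[totals == 0])
        raise ValueError(f"library with zero total counts: {zero}")
    return counts / totals * 1e6


def condition_tpm(cm: CountMatrix, condition: str) -> pd.Series:
    """Replicate-mean tpm for one condition."""
    cols = cm.samples_for(condition)
    if not cols:
        raise ValueError(f"no samples for condition {condition!r}")
    return tpm_normalize(cm.counts[cols]).mean(axis=1)


# ---------------------------------------------------------------------------
# Report metrics

def log2_fold_change(tpm_control: float, tpm_heat: float) -> float:
    """log2(heat/control); +/-inf when exactly one side is zero, 0 when both."""
    if tpm_control < 0 or tpm_heat < 0:
        raise ValueError("tpm values must be non-negative")
    if tpm_control == 0 and tpm_heat == 0:
        return 0.0
    if tpm_control == 0:
        return float("inf")
    if tpm_heat == 0:
        return float("-inf")
    return float(np.log2(tpm_heat / tpm_control))


def percent_change(tpm_control: float, tpm_heat: float) -> float:
    """Heat-vs-control change in percent: 100 * (H - C) / max(C, H).

    Positive values mean enhancement under heat, negative reduction; the
    denominator is the larger of the two so the result is bounded by
    (-100, 100].
    """
    if tpm_control < 0 or tpm_heat < 0:
        raise ValueError("tpm values must be non-negative")
    denom = max(tpm_control, tpm_heat)
    if denom == 0:
        warnings.warn("percent_change of (0, 0) reported as 0")
        return 0.0
    # mathematically bounded by [-100, 100]; clamp float roundoff
    return min(max(100.0 * (tpm_heat - tpm_control) / denom, -100.0), 100.0)


def delta_delta_ct(ct_target_a: float, ct_ref_a: float,
                   ct_target_b: float, ct_ref_b: float) -> float:
    """qPCR relative quantification: 2^-ddCt of sample b vs sample a."""
    for v in (ct_target_a, ct_ref_a, ct_target_b, ct_ref_b):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_b - ct_ref_b) - (ct_target_a - ct_ref_a)
    return float(2.0 ** (-ddct))


# ---------------------------------------------------------------------------
# Multiple testing

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR, order-preserving w.r.t. input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    fdr = np.empty(m)
    fdr[order] = np.minimum(ranked, 1.0)
    return fdr


# ---------------------------------------------------------------------------
# Dispersion estimation

def _moments_dispersion(norm_counts: np.ndarray, groups: list[np.ndarray],
                        inv_sf_mean: float) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments per-feature dispersion from normalized counts.

    Pools within-condition variances, subtracts the shot-noise term
    (baseMean * mean(1/s_j)), and divides by baseMean^2.
    """
    q = norm_counts.mean(axis=1)
    # pooled within-condition variance
    ss = np.zeros(norm_counts.shape[0])
    dof = 0
    for idx in groups:
        sub = norm_counts[:, idx]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        dof += len(idx) - 1
    if dof <= 0:
        raise ValueError("need at least one condition with >= 2 replicates")
    w = ss / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (w - q * inv_sf_mean) / q**2
    alpha[~np.isfinite(alpha)] = 0.0
    return q, alpha


def _fit_dispersion_trend(q: np.ndarray, alpha: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of the parametric trend alpha(q) = a0 + a1/q."""
    mask = (q > 0) & (alpha > 0)
    if mask.sum() < 2:
        return 0.0, 0.0
    x = 1.0 / q[mask]
    y = alpha[mask]
    a1, a0 = np.polyfit(x, y, 1)
    return max(a0, 0.0), max(a1, 0.0)


# ---------------------------------------------------------------------------
# Exact NB test

def _split_pvalue(ka: int, kb: int, mu_a: float, mu_b: float,
                  var_a: float, var_b: float) -> float:
    """Two-sided exact p over all splits (a, b) with a + b = ka + kb.

    p = sum of P(a)P(b) over splits whose probability does not exceed the
    observed split's, normalized by the sum over all splits.
    """
    total = ka + kb
    if total == 0:
        return 1.0
    a = np.arange(total + 1)
    logp_a = _nb_logpmf(a, mu_a, var_a)
    logp_b = _nb_logpmf(total - a, mu_b, var_b)
    logp = logp_a + logp_b
    log_obs = logp[ka]
    # log-sum-exp over the <= observed set and over everything
    mx = logp.max()
    probs = np.exp(logp - mx)
    denom = probs.sum()
    num = probs[logp <= log_obs + 1e-12].sum()
    return float(min(num / denom, 1.0))


def _nb_logpmf(k: np.ndarray, mu: float, var: float) -> np.ndarray:
    """NB log-pmf parameterized by mean/variance; Poisson when var <= mu."""
    k = np.asarray(k, dtype=float)
    if mu <= 0:
        out = np.full(k.shape, -np.inf)
        out[k == 0] = 0.0
        return out
    if var <= mu * (1 + 1e-8):
        return k * np.log(mu) - mu - gammaln(k + 1)
    r = mu**2 / (var - mu)
    p = r / (r + mu)
    return sps.nbinom.logpmf(k, r, p)


def nb_test(cm: CountMatrix, condition_a: str = "control",
            condition_b: str = "heat",
            dispersion: float | str = "trend") -> pd.DataFrame:
    """Per-feature two-sided exact NB test between two conditions.

    ``dispersion`` is either a fixed value (0 gives the Poisson limit), or
    ``"trend"`` (method-of-moments floored at the fitted a0 + a1/q trend) or
    ``"per-feature"`` (raw moments estimate, floored at zero).

    Returns a DataFrame with columns id, baseMeanA, baseMeanB, log2fc, pval,
    fdr; all-zero features get p = 1, log2fc = 0 and are flagged.
    """
    cols_a = cm.samples_for(condition_a)
    cols_b = cm.samples_for(condition_b)
    if not cols_a or not cols_b:
        raise ValueError("both conditions need at least one sample")

    counts = cm.counts[cols_a + cols_b]
    sf = size_factors(counts)
    norm = counts.to_numpy(dtype=float) / sf.to_numpy()
    na, nb_ = len(cols_a), len(cols_b)
    idx_a = np.arange(na)
    idx_b = np.arange(na, na + nb_)

    q = norm.mean(axis=1)
    mean_a = norm[:, idx_a].mean(axis=1)
    mean_b = norm[:, idx_b].mean(axis=1)

    if isinstance(dispersion, str):
        q_all, alpha_raw = _moments_dispersion(
            norm, [idx_a, idx_b], float((1.0 / sf).mean()))
        if dispersion == "trend":
            a0, a1 = _fit_dispersion_trend(q_all, alpha_raw)
            with np.errstate(divide="ignore"):
                trend = np.where(q_all > 0, a0 + a1 / np.maximum(q_all, 1e-12), 0.0)
            alpha = np.maximum(alpha_raw, trend)
        elif dispersion == "per-feature":
            alpha = np.maximum(alpha_raw, 0.0)
        else:
            raise ValueError(f"unknown dispersion method {dispersion!r}")
    else:
        if dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        alpha = np.full(counts.shape[0], float(dispersion))

    sf_a = sf.iloc[idx_a].to_numpy()
    sf_b = sf.iloc[idx_b].to_numpy()
    ka = counts[cols_a].sum(axis=1).to_numpy()
    kb = counts[cols_b].sum(axis=1).to_numpy()

    rows = []
    for i, fid in enumerate(counts.index):
        if ka[i] + kb[i] == 0:
            rows.append((fid, 0.0, 0.0, 0.0, 1.0, True))
            continue
        mu_a = q[i] * sf_a.sum()
        mu_b = q[i] * sf_b.sum()
        var_a = mu_a + alpha[i] * q[i] ** 2 * (sf_a**2).sum()
        var_b = mu_b + alpha[i] * q[i] ** 2 * (sf_b**2).sum()
        p = _split_pvalue(int(ka[i]), int(kb[i]), mu_a, mu_b, var_a, var_b)
        lfc = log2_fold_change(mean_a[i], mean_b[i])
        rows.append((fid, mean_a[i], mean_b[i], lfc, p, False))

    out = pd.DataFrame(rows, columns=["id", "baseMeanA", "baseMeanB",
                                      "log2fc", "pval", "all_zero"])
    out["fdr"] = bh_adjust(out["pval"].to_numpy())
    return out[["id", "baseMeanA", "baseMeanB", "log2fc", "pval", "fdr",
                "all_zero"]]
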