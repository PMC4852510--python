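"""Statistical primitives for probe-level change calls and count-based DE.

The change-call machinery mirrors the classic microarray comparison call:
per transcript, paired probe-level log2 differences between two samples are
tested with a one-sided Wilcoxon signed-rank test, and a transcript is
called Increased / Decreased / NoChange per comparison. Calls are then
required to be consistent across replicate comparisons.

The count-based differential test is a deliberately simple negative-binomial
procedure in the style of the original DEseq: median-of-ratios size factors,
method-of-moments dispersions moderated by a fitted mean–dispersion trend,
and a conditioned exact test on the per-group totals. It aims at the same
qualitative behaviour, not bit-compatibility with any released tool.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

INCREASE = "I"
DECREASE = "D"
NO_CHANGE = "NC"


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds for change calls and differential expression.

    alpha      one-sided signed-rank p-value cutoff per comparison
    lfc        absolute log2 fold-change gate (1.5 ~ 2.8-fold)
    de_fdr     BH-adjusted p cutoff for the count-based DE test
    floor      intensity floor applied before log2 (avoids infinite ratios)
    """

    alpha: float = 0.05
    lfc: float = 1.5
    de_fdr: float = 0.10
    floor: float = 8.0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.lfc <= 0:
            raise ValueError("lfc must be positive")


@dataclass(frozen=True)
class ChangeCall:
    """Per-transcript, per-comparison change decision."""

    transcript_id: str
    comparison: str
    call: str  # one of I / D / NC
    p: float  # one-sided signed-rank p (NaN when undefined)
    log2_ratio: float
    flagged: bool = False


@dataclass
class DEResult:
    gene_id: str
    base_mean: float
    log2_fc: float
    p: float
    padj: float = float("nan")

    @property
    def direction(self) -> str:
        if self.log2_fc < 0:
            return DECREASE
        if self.log2_fc > 0:
            return INCREASE
        return NO_CHANGE


# ---------------------------------------------------------------------------
# probe summarization
# ---------------------------------------------------------------------------

def summarize_probes(probe_values: pd.DataFrame, probe_map: pd.Series,
                     floor: float = 8.0) -> tuple[pd.DataFrame, pd.Series]:
    """Summarize probe intensities to transcript-level log2 expression.

    Parameters
    ----------
    probe_values
        Probes x samples matrix of linear-scale intensities.
    probe_map
        probe id -> transcript id; every probe must be mapped.
    floor
        Intensities are floored here before taking log2.

    Returns
    -------
    (transcript log2 matrix, flags) where ``flags[t]`` is True for
    transcripts summarized from fewer than 3 probes.
    """
    unmapped = probe_values.index.difference(probe_map.index)
    if len(unmapped):
        raise ValueError(f"unmapped probes: {list(unmapped[:5])}")
    log2 = np.log2(probe_values.clip(lower=floor))
    groups = probe_map.reindex(probe_values.index)
    summarized = log2.groupby(groups).mean()
    n_probes = log2.groupby(groups).size()
    flags = n_probes < 3
    flags.name = "few_probes"
    return summarized, flags


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=4096)
def _exact_tail_table(ranks2: tuple[int, ...]) -> tuple[np.ndarray, int]:
    """Null distribution of 2*W+ under sign randomization, for tied ranks.

    ``ranks2`` are ranks doubled to integers (average ties give .5 steps).
    Returns (counts over achievable 2*W+ values 0..sum, total 2^n).
    """
    total = sum(ranks2)
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts, 2 ** len(ranks2)


def signed_rank_test(diffs, direction: str = "greater",
                     exact_max_n: int = 12) -> tuple[float, float]:
    """One-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are discarded (the classic reduced-sample treatment).
    For n <= ``exact_max_n`` the p-value is the exact tail probability of
    W+ = sum of ranks of positive differences under sign randomization,
    computed from the full null distribution (ties handled by average
    ranks). For larger n a normal approximation with tie correction and a
    continuity correction is used.

    Returns ``(W, p)``; if every difference is zero the pair is
    uninformative and ``(0.0, nan)`` is returned (NoChange sentinel).
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, float("nan")
    ranks = sps.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        ranks2 = tuple(sorted(int(round(2 * r)) for r in ranks))
        counts, denom = _exact_tail_table(ranks2)
        w2 = int(round(2 * w))
        if direction == "greater":
            p = counts[w2:].sum() / denom
        else:
            p = counts[: w2 + 1].sum() / denom
        return w, float(p)
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    sd = np.sqrt(var)
    if direction == "greater":
        p = sps.norm.sf((w - mean - 0.5) / sd)
    else:
        p = sps.norm.cdf((w - mean + 0.5) / sd)
    return w, float(min(max(p, 0.0), 1.0))


def change_call(probe_values_a, probe_values_b, thresholds: Thresholds,
                transcript_id: str = "", comparison: str = "") -> ChangeCall:
    """Call Increase/Decrease/NoChange for sample B relative to sample A.

    Both arrays hold linear-scale intensities for the same probes in the
    same order. The call is made on paired log2 differences (B - A); the
    reported log2_ratio is the difference of the summarized (mean log2)
    values, so shared probe-affinity offsets cancel.
    """
    a = np.log2(np.clip(np.asarray(probe_values_a, float), thresholds.floor, None))
    b = np.log2(np.clip(np.asarray(probe_values_b, float), thresholds.floor, None))
    if a.shape != b.shape:
        raise ValueError("probe sets differ between samples")
    diffs = b - a
    log2_ratio = float(np.mean(diffs))
    if a.size < 3:
        return ChangeCall(transcript_id, comparison, NO_CHANGE,
                          float("nan"), log2_ratio, flagged=True)
    _, p_greater = signed_rank_test(diffs, "greater")
    _, p_less = signed_rank_test(diffs, "less")
    if np.isnan(p_greater):  # all differences zero
        return ChangeCall(transcript_id, comparison, NO_CHANGE,
                          float("nan"), log2_ratio)
    if p_greater < thresholds.alpha:
        return ChangeCall(transcript_id, comparison, INCREASE, p_greater, log2_ratio)
    if p_less < thresholds.alpha:
        return ChangeCall(transcript_id, comparison, DECREASE, p_less, log2_ratio)
    return ChangeCall(transcript_id, comparison, NO_CHANGE,
                      float(min(p_greater, p_less)), log2_ratio)


def consistent_call(calls) -> str:
    """Collapse replicate comparisons: I (or D) only if every call agrees."""
    calls = [c.call if isinstance(c, ChangeCall) else c for c in calls]
    if not calls:
        raise ValueError("no comparisons given")
    if len(calls) < 2:
        raise ValueError("need >=2 replicate comparisons")
    first = calls[0]
    if first in (INCREASE, DECREASE) and all(c == first for c in calls):
        return first
    return NO_CHANGE


def group_shift_test(log2_ratios) -> float:
    """Two-sided signed-rank test of a gene set's log2 ratios against 0.

    Used to ask whether a whole set of transcripts shifts up or down in a
    comparison. Note the discreteness floor: with n genes the smallest
    achievable two-sided p is 2/2^n (0.125 at n = 4).
    """
    r = np.asarray(log2_ratios, dtype=float)
    if r.size == 0:
        raise ValueError("empty gene set")
    _, p_greater = signed_rank_test(r, "greater")
    _, p_less = signed_rank_test(r, "less")
    if np.isnan(p_greater):
        return 1.0
    return float(min(1.0, 2.0 * min(p_greater, p_less)))


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    NaN entries propagate as NaN and are excluded from the number of tests.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        if (p[mask] < 0).any() or (p[mask] > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# count-based differential expression
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample column.

    For each gene with nonzero counts in every sample, compute the ratio of
    its count to its geometric mean across samples; the size factor is the
    per-sample median of those ratios.
    """
    c = counts.to_numpy(dtype=float)
    all_nonzero = (c > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; consider a "
            "pseudo-reference or filtering samples")
    sub = c[all_nonzero]
    log_geo_mean = np.log(sub).mean(axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(sub) - log_geo_mean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _nb_logpmf(k, mean, dispersion):
    """NB log-pmf parameterized by mean and dispersion (var = mu + a*mu^2)."""
    if dispersion <= 1e-8:
        return sps.poisson.logpmf(k, mean)
    size = 1.0 / dispersion
    prob = size / (size + mean)
    return sps.nbinom.logpmf(k, size, prob)


def _conditioned_exact_p(k_t: int, k_c: int, n_t: int, n_c: int,
                         dispersion: float) -> float:
    """Two-sided conditioned NB exact test on group totals.

    Conditions on the grand total k_t + k_c: under the null both groups
    share a common per-sample mean, so the treated total is NB with mean
    proportional to its sample count. The p-value sums the probabilities of
    all splits as or less likely than the observed one.
    """
    total = k_t + k_c
    if total == 0:
        return 1.0
    mu = total / (n_t + n_c)
    a = np.arange(total + 1)
    # group totals: sums of iid NB have the per-sample dispersion scaled down
    lp = (_nb_logpmf(a, n_t * mu, dispersion / n_t)
          + _nb_logpmf(total - a, n_c * mu, dispersion / n_c))
    lp -= logsumexp(lp)  # renormalize: condition on the observed total
    p_obs = lp[k_t]
    keep = lp <= p_obs + 1e-12
    return float(min(1.0, np.exp(logsumexp(lp[keep]))))


def _dispersion_estimates(norm_counts: np.ndarray, groups: list[np.ndarray]
                          ) -> np.ndarray:
    """Per-gene dispersions: max(method-of-moments, fitted trend).

    The raw estimate pools within-group moments; the trend is a least-squares
    line on log dispersion vs log mean over genes with positive raw
    estimates, which moderates the noisy per-gene values from few replicates.
    """
    mu = norm_counts.mean(axis=1)
    within_var = np.mean(
        [norm_counts[:, g].var(axis=1, ddof=1) for g in groups], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (within_var - mu) / np.maximum(mu, 1e-8) ** 2
    ok = np.isfinite(raw) & (mu > 0)
    # trend fit on pooled (binned) moment estimates: per-gene estimates from
    # few replicates are far too noisy (and log-transforming them biases the
    # fit low); the ratio-of-sums estimator per mean-bin is nearly unbiased
    bins = max(3, min(20, int(ok.sum() // 50)))
    xs, ys = [], []
    if ok.sum() >= 30:
        order = np.argsort(mu[ok])
        mu_ok = mu[ok][order]
        var_ok = within_var[ok][order]
        for chunk_mu, chunk_var in zip(np.array_split(mu_ok, bins),
                                       np.array_split(var_ok, bins)):
            alpha_bin = (chunk_var - chunk_mu).sum() / (chunk_mu**2).sum()
            if alpha_bin > 0:
                xs.append(np.log(chunk_mu.mean()))
                ys.append(np.log(alpha_bin))
    if len(xs) >= 2:
        slope, intercept = np.polyfit(xs, ys, 1)
        trend = np.exp(intercept + slope * np.log(np.maximum(mu, 1e-8)))
    elif len(xs) == 1:
        trend = np.full_like(mu, np.exp(ys[0]))
    else:
        trend = np.full_like(mu, 0.01)
    disp = np.maximum(np.nan_to_num(raw, nan=0.0), trend)
    return np.clip(disp, 1e-8, 10.0)


def nb_de_test(counts: pd.DataFrame, groups: dict[str, list[str]],
               thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Differential expression between two groups of count columns.

    Parameters
    ----------
    counts
        Genes x samples integer count matrix.
    groups
        ``{"treated": [cols], "control": [cols]}`` with >=2 replicates each.

    Returns
    -------
    DataFrame with columns base_mean, log2_fc (treated over control), p,
    padj and direction, indexed by gene. Decreased genes at the configured
    FDR are ``padj <= de_fdr`` and ``log2_fc < 0``.
    """
    thresholds = thresholds or Thresholds()
    t_cols, c_cols = groups["treated"], groups["control"]
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise ValueError("need >=2 replicates per group")
    sf = size_factors(counts[t_cols + c_cols])
    norm = counts[t_cols + c_cols].to_numpy(float) / sf.to_numpy()
    n_t, n_c = len(t_cols), len(c_cols)
    t_idx = np.arange(n_t)
    c_idx = np.arange(n_t, n_t + n_c)
    disp = _dispersion_estimates(norm, [t_idx, c_idx])
    mu_t = norm[:, t_idx].mean(axis=1)
    mu_c = norm[:, c_idx].mean(axis=1)
    log2_fc = np.log2(np.maximum(mu_t, 0.5) / np.maximum(mu_c, 0.5))
    base_mean = norm.mean(axis=1)

    # pseudo-totals on the common (normalized) scale, rounded to integers
    k_t = np.rint(norm[:, t_idx].sum(axis=1)).astype(int)
    k_c = np.rint(norm[:, c_idx].sum(axis=1)).astype(int)
    pvals = np.ones(len(counts))
    for i in range(len(counts)):
        if k_t[i] + k_c[i] == 0:
            continue
        var_all = norm[i].var(ddof=1)
        if var_all == 0 and mu_t[i] == mu_c[i]:
            pvals[i] = 1.0
            continue
        pvals[i] = _conditioned_exact_p(k_t[i], k_c[i], n_t, n_c, disp[i])
    padj = bh_fdr(pvals)
    out = pd.DataFrame({
        "base_mean": base_mean,
        "log2_fc": log2_fc,
        "p": pvals,
        "padj": padj,
    }, index=counts.index)
    out["direction"] = np.where(
        (out["padj"] <= thresholds.de_fdr) & (out["log2_fc"] < 0), DECREASE,
        np.where((out["padj"] <= thresholds.de_fdr) & (out["log2_fc"] > 0),
                 INCREASE, NO_CHANGE))
    return out
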