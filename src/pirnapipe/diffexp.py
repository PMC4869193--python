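"""Per-cluster differential expression between two sample groups.

This is a documented lightweight stand-in for a full shrinkage-GLM DE stack:
median-of-ratios size factors, per-cluster method-of-moments negative-
binomial dispersion shrunk toward a trended mean-dispersion fit, and a
two-sided conditional exact NB test on group sums (the classic exact test
for two NB groups), with a Poisson/binomial fallback whenever the estimated
variance does not exceed the mean. Externally computed per-cluster p-values
can be substituted to reproduce an exact third-party stack.

Filters follow the two-stage convention: an *expression filter* (at least
one group mean raw count > 10 and |log2FC| > 2) gates which fold changes
are considered at all, and the *DE filter* (fold change > 4, i.e.
|log2FC| > 2, with p < 0.05) defines significance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CountMatrix

PRIOR_DISPERSION = 0.1  # used when no group has replicates
PRIOR_DF = 10.0  # strength of shrinkage toward the trend


@dataclass
class DEResult:
    cluster_id: str
    mean_a: float
    mean_b: float
    log2fc: float
    p_value: float
    passes_expression_filter: bool
    passes_de_filter: bool


def size_factors(matrix: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    factor_j = median over clusters of count_ij / geometric-mean_i, taken over
    clusters whose geometric mean is nonzero.
    """
    counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    arr = counts.to_numpy(dtype=float)
    if arr.size == 0 or not (arr > 0).any():
        raise ValueError("all-zero count matrix")
    if arr.shape[1] < 2:
        raise ValueError("size factors need >= 2 samples")
    with np.errstate(divide="ignore"):
        log_gm = np.mean(np.log(arr), axis=1)  # -inf where any zero
    usable = np.isfinite(log_gm)
    if not usable.any():
        raise ValueError("no cluster has nonzero counts in every sample")
    ratios = arr[usable] / np.exp(log_gm[usable])[:, None]
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns)


def _mom_dispersion(norm: np.ndarray, groups: list[np.ndarray]) -> float | None:
    """Pooled method-of-moments NB dispersion; None without replicates."""
    num = den = 0.0
    any_rep = False
    for idx in groups:
        x = norm[idx]
        if len(x) < 2:
            continue
        any_rep = True
        mu = x.mean()
        if mu <= 0:
            continue
        var = x.var(ddof=1)
        num += (len(x) - 1) * (var - mu) / (mu * mu)
        den += len(x) - 1
    if not any_rep or den == 0:
        return None
    return max(num / den, 0.0)


def _trend_fit(means: np.ndarray, disps: np.ndarray) -> tuple[float, float]:
    """Fit dispersion = a1 + a0/mean by least squares (both clipped at 0)."""
    ok = (means > 0) & np.isfinite(disps)
    if ok.sum() < 2:
        d = float(np.median(disps[ok])) if ok.any() else PRIOR_DISPERSION
        return 0.0, max(d, 0.0)
    X = np.column_stack([1.0 / means[ok], np.ones(ok.sum())])
    coef, *_ = np.linalg.lstsq(X, disps[ok], rcond=None)
    return max(float(coef[0]), 0.0), max(float(coef[1]), 0.0)


def nb_exact_test(
    sum_a: float, sum_b: float, n_a: int, n_b: int, dispersion: float
) -> float:
    """Two-sided conditional exact test for equality of two NB group means.

    Group sums are modelled as NB with per-sample dispersion ``dispersion``
    (a sum of n iid NB(r, p) is NB(n*r, p)); conditioning on the total, the
    two-sided p-value aggregates all splits no more likely than the observed
    one. ``dispersion <= 0`` falls back to the Poisson case, where the
    conditional law is binomial.
    """
    sa, sb = int(round(sum_a)), int(round(sum_b))
    s = sa + sb
    if s == 0:
        return 1.0
    if dispersion <= 1e-12:
        k = np.arange(s + 1)
        pmf = stats.binom.pmf(k, s, n_a / (n_a + n_b))
    else:
        r = 1.0 / dispersion
        mu = s / (n_a + n_b)
        p = r / (r + mu)
        k = np.arange(s + 1)
        pmf = stats.nbinom.pmf(k, n_a * r, p) * stats.nbinom.pmf(s - k, n_b * r, p)
        total = pmf.sum()
        if total <= 0:
            return 1.0
        pmf = pmf / total
    observed = pmf[sa]
    p = float(min(1.0, pmf[pmf <= observed * (1 + 1e-12)].sum()))
    return 1.0 if p > 1.0 - 1e-9 else p


def differential_expression(
    matrix: CountMatrix,
    group_a: Sequence[str] | str,
    group_b: Sequence[str] | str,
    pseudocount: float = 0.5,
    expression_min: float = 10.0,
    log2fc_min: float = 2.0,
    alpha: float = 0.05,
    external_pvalues: Mapping[str, float] | None = None,
) -> list[DEResult]:
    """Per-cluster log2 fold change (B over A) and exact-test p-value.

    Groups may be given as sample-id lists or as role names. log2FC uses
    normalized group means with a pseudocount; the expression filter uses raw
    group means. ``external_pvalues`` substitutes precomputed p-values while
    keeping the fold-change and filter logic.
    """
    ids_a = _resolve_group(matrix, group_a)
    ids_b = _resolve_group(matrix, group_b)

    counts = matrix.counts
    factors = size_factors(counts[list(dict.fromkeys([*ids_a, *ids_b]))])
    norm = counts[factors.index] / factors

    ia = [list(factors.index).index(s) for s in ids_a]
    ib = [list(factors.index).index(s) for s in ids_b]
    norm_arr = norm.to_numpy(dtype=float)
    raw_arr = counts[factors.index].to_numpy(dtype=float)

    base_means = norm_arr[:, ia + ib].mean(axis=1)
    mom = np.array(
        [
            d if (d := _mom_dispersion(row, [np.array(ia), np.array(ib)])) is not None
            else np.nan
            for row in norm_arr
        ]
    )
    a0, a1 = _trend_fit(base_means, mom)
    trend = np.where(base_means > 0, a1 + a0 / np.maximum(base_means, 1e-9), a1)

    # residual df for the moment estimate; shrink harder when replication is thin
    df = max(len(ia) - 1, 0) + max(len(ib) - 1, 0)
    w = df / (df + PRIOR_DF)

    results = []
    for i, cid in enumerate(matrix.cluster_ids):
        mean_a_norm = norm_arr[i, ia].mean()
        mean_b_norm = norm_arr[i, ib].mean()
        mean_a_raw = raw_arr[i, ia].mean()
        mean_b_raw = raw_arr[i, ib].mean()
        log2fc = float(
            np.log2((mean_b_norm + pseudocount) / (mean_a_norm + pseudocount))
        )
        if external_pvalues is not None:
            p = float(external_pvalues[cid])
        else:
            if np.isnan(mom[i]):
                disp = PRIOR_DISPERSION if df == 0 else trend[i]
            else:
                disp = w * mom[i] + (1 - w) * trend[i]
            p = nb_exact_test(
                norm_arr[i, ia].sum(), norm_arr[i, ib].sum(), len(ia), len(ib), disp
            )
        expr = (
            max(mean_a_raw, mean_b_raw) > expression_min and abs(log2fc) > log2fc_min
        )
        de = abs(log2fc) > log2fc_min and p < alpha
        results.append(
            DEResult(cid, mean_a_norm, mean_b_norm, log2fc, p, expr, de)
        )
    return results


def _resolve_group(matrix: CountMatrix, group: Sequence[str] | str) -> list[str]:
    if isinstance(group, str):
        ids = matrix.samples_with_role(group)
        if not ids:
            ids = [s for s in matrix.sample_ids if s == group]
        if not ids:
            raise ValueError(f"group {group!r} matches no samples")
        return ids
    missing = [s for s in group if s not in matrix.sample_ids]
    if missing:
        raise ValueError(f"samples not in matrix: {missing}")
    if not group:
        raise ValueError("empty group")
    return list(group)


@dataclass
class DEAccounting:
    n_down: int
    n_up: int
    pct_down: float
    pct_up: float
    n_tested: int


def accounting_from_counts(n_down: int, n_up: int, n_tested: int) -> DEAccounting:
    """Percentages of down/up-regulated clusters, rounded to one decimal."""
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    return DEAccounting(
        n_down=n_down,
        n_up=n_up,
        pct_down=round(100.0 * n_down / n_tested, 1),
        pct_up=round(100.0 * n_up / n_tested, 1),
        n_tested=n_tested,
    )


def de_accounting(results: Sequence[DEResult]) -> DEAccounting:
    """Count clusters passing the DE filter per direction (down = B below A)."""
    n_down = sum(1 for r in results if r.passes_de_filter and r.log2fc < 0)
    n_up = sum(1 for r in results if r.passes_de_filter and r.log2fc > 0)
    return accounting_from_counts(n_down, n_up, len(results))


def results_to_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster_id": [r.cluster_id for r in results],
            "mean_a": [r.mean_a for r in results],
            "mean_b": [r.mean_b for r in results],
            "log2fc": [r.log2fc for r in results],
            "p_value": [r.p_value for r in results],
            "passes_expression_filter": [r.passes_expression_filter for r in results],
            "passes_de_filter": [r.passes_de_filter for r in results],
        }
    )
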