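"""Cross-sectional group comparisons and correlations with FDR control.

Wilcoxon-Mann-Whitney rank-sum tests between disease stages, Spearman
correlations of composites against TI/TSS within stage, and Benjamini-
Hochberg adjustment at FDR 0.05. The rank-sum p-value is exact (full
enumeration of the rank-sum null distribution) when both samples have at
most 8 observations and there are no ties, and a tie-corrected normal
approximation otherwise.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import COMPOSITES

__all__ = [
    "wilcoxon_mw",
    "spearman",
    "bh_adjust",
    "run_baseline_battery",
    "EXACT_MAX_N",
]

#: Largest per-sample size for the exact rank-sum branch.
EXACT_MAX_N = 8


def _rank_sum_distribution(n1: int, n: int) -> np.ndarray:
    """P(rank sum of sample 1 = s) for s = 0..n1*n - offset, by DP.

    Counts subsets of {1..n} of size n1 by sum; returned array is indexed by
    (sum - min_sum) where min_sum = n1(n1+1)/2.
    """
    max_sum = n1 * n
    counts = np.zeros((n1 + 1, max_sum + 1))
    counts[0, 0] = 1.0
    for value in range(1, n + 1):
        for k in range(min(n1, value), 0, -1):
            counts[k, value:] += counts[k - 1, :-value or None]
    dist = counts[n1]
    min_sum = n1 * (n1 + 1) // 2
    dist = dist[min_sum:n1 * n - min_sum + min_sum + 1]
    return dist / dist.sum()


def wilcoxon_mw(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Rank-sum test; returns (U statistic of ``x``, two-sided p).

    Exact enumeration when both n <= 8 and the pooled data has no ties;
    otherwise normal approximation with midranks, tie correction and
    continuity correction. Two identical samples give p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical across both samples; p = 1")
        return x.size * y.size / 2.0, 1.0
    ranks = sps.rankdata(pooled)
    r1 = ranks[:x.size].sum()
    u1 = r1 - x.size * (x.size + 1) / 2.0
    n1, n2 = x.size, y.size
    ties = np.unique(pooled, return_counts=True)[1]
    no_ties = np.all(ties == 1)
    if no_ties and n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        dist = _rank_sum_distribution(n1, n1 + n2)
        idx = int(round(r1)) - n1 * (n1 + 1) // 2
        lower = dist[:idx + 1].sum()
        upper = dist[idx:].sum()
        p = min(1.0, 2.0 * min(lower, upper))
        return float(u1), float(p)
    mu = n1 * n2 / 2.0
    n = n1 + n2
    tie_term = ((ties ** 3 - ties).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        warnings.warn("degenerate rank variance; p = 1")
        return float(u1), 1.0
    z = (u1 - mu - np.sign(u1 - mu) * 0.5) / np.sqrt(sigma2)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(u1), float(min(1.0, p))


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Spearman correlation with pairwise-complete deletion.

    Returns (rho, p, n). Undefined correlations (n < 3 or zero rank
    variance) are reported as (nan, nan, n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), n
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p), n


def bh_adjust(p_values: Sequence[float], q: float = 0.05):
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted p array, rejection flags at FDR ``q``) in the original
    order; adj_i = min over j >= i (by p-rank) of m * p_(j) / j, clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    finite = p[np.isfinite(p)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    adj = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m:
        order = np.argsort(p[ok], kind="stable")
        ranked = p[ok][order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        vals = np.minimum(ranked, 1.0)
        tmp = np.empty(m)
        tmp[order] = vals
        adj[ok] = tmp
    reject = np.where(np.isfinite(adj), adj <= q, False)
    return adj, reject


_STAGE_PAIRS = (("OC", "Preclinical"), ("OC", "Symptomatic"),
                ("Preclinical", "Symptomatic"))


def run_baseline_battery(baseline: pd.DataFrame, q: float = 0.05,
                         composites: Sequence[str] = COMPOSITES,
                         metrics: Sequence[str] = ("TI", "TSS")):
    """The full cross-sectional battery on a staged baseline table.

    ``baseline`` needs one row per participant with ``stage``, the composite
    columns, and the tau metric columns. Two tidy tables are returned:

    * pairwise stage comparisons — for each outcome (5 composites + TI +
      TSS), the three stage-pairwise rank-sum tests, BH-adjusted within that
      outcome's family of three;
    * correlations — per stage, Spearman of each composite against each
      metric, BH-adjusted within the stage's family of 10.

    Cells with fewer than 3 usable observations are reported as insufficient
    rather than failing the battery.
    """
    outcomes = list(composites) + list(metrics)
    groups = {s: g for s, g in baseline.groupby("stage")}

    test_rows = []
    for outcome in outcomes:
        fam = []
        for a, b in _STAGE_PAIRS:
            xa = groups.get(a, pd.DataFrame()).get(outcome, pd.Series(dtype=float)).dropna()
            xb = groups.get(b, pd.DataFrame()).get(outcome, pd.Series(dtype=float)).dropna()
            if len(xa) < 3 or len(xb) < 3:
                fam.append({"outcome": outcome, "group_a": a, "group_b": b,
                            "n_a": len(xa), "n_b": len(xb), "statistic": np.nan,
                            "p_raw": np.nan, "note": "insufficient"})
                continue
            u, p = wilcoxon_mw(xa.to_numpy(), xb.to_numpy())
            fam.append({"outcome": outcome, "group_a": a, "group_b": b,
                        "n_a": len(xa), "n_b": len(xb), "statistic": u,
                        "p_raw": p, "note": ""})
        adj, rej = bh_adjust([r["p_raw"] for r in fam], q)
        for r, a_, j in zip(fam, adj, rej):
            r["p_bh"], r["significant"] = a_, bool(j)
        test_rows.extend(fam)

    corr_rows = []
    for stage in ("OC", "Preclinical", "Symptomatic"):
        g = groups.get(stage, pd.DataFrame())
        fam = []
        for comp, metric in ((c, m) for c in composites for m in metrics):
            if comp in g.columns and metric in g.columns:
                rho, p, n = spearman(g[comp].to_numpy(float),
                                     g[metric].to_numpy(float))
            else:
                rho, p, n = np.nan, np.nan, 0
            fam.append({"stage": stage, "composite": comp, "metric": metric,
                        "rho": rho, "n": n, "p_raw": p,
                        "note": "" if np.isfinite(p) else "insufficient"})
        adj, rej = bh_adjust([r["p_raw"] for r in fam], q)
        for r, a_, j in zip(fam, adj, rej):
            r["p_bh"], r["significant"] = a_, bool(j)
        corr_rows.extend(fam)

    return pd.DataFrame(test_rows), pd.DataFrame(corr_rows)
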