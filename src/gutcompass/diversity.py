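"""Alpha diversity (Shannon index) and pairwise cohort comparison.

Shannon's H = -sum p_i ln p_i is computed in nats per sample at species
level; cohorts are compared pairwise with the Wilcoxon rank-sum test and
Benjamini-Hochberg correction across pairs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AbundanceTable, GutcompassError, SampleMetadata

__all__ = [
    "shannon",
    "shannon_per_sample",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "DiversityResult",
    "diversity_analysis",
]

#: exact Wilcoxon enumeration is used automatically up to this combined size
EXACT_LIMIT = 12


def shannon(proportions) -> float:
    """Shannon index H (nats) of one sample; renormalizes internally."""
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise GutcompassError("negative entries in abundance vector")
    if p.sum() <= 0:
        raise GutcompassError("all-zero abundance vector has no Shannon index")
    return float(stats.entropy(p))  # natural log, 0*ln 0 = 0, renormalizes


def shannon_per_sample(table: AbundanceTable) -> pd.Series:
    vals = table.proportions().to_numpy()
    h = np.array([shannon(row) for row in vals])
    return pd.Series(h, index=table.data.index, name="shannon")


def _rank_sum_u(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x relative to y with midranks for ties."""
    ranks = stats.rankdata(np.concatenate([x, y]))
    rx = ranks[: len(x)].sum()
    return float(rx - len(x) * (len(x) + 1) / 2.0)


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    ``mode='exact'`` enumerates all C(m+n, m) group assignments of the pooled
    values — valid with ties, feasible for small samples.  ``mode='approx'``
    uses the normal approximation with tie and continuity corrections.
    ``'auto'`` picks exact when m + n <= 12.

    Returns (U statistic for x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise GutcompassError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical across both groups; p = 1")
        return _rank_sum_u(x, y), 1.0
    if mode == "auto":
        mode = "exact" if x.size + y.size <= EXACT_LIMIT else "approx"
    if mode == "exact":
        m, n = x.size, y.size
        u_obs = _rank_sum_u(x, y)
        mid = m * n / 2.0
        total = comb(m + n, m)
        hits = 0
        idx_all = range(m + n)
        for combo in itertools.combinations(idx_all, m):
            mask = np.zeros(m + n, dtype=bool)
            mask[list(combo)] = True
            u = _rank_sum_u(pooled[mask], pooled[~mask])
            # two-sided: as or more extreme in distance from the null mean
            if abs(u - mid) >= abs(u_obs - mid) - 1e-12:
                hits += 1
        return u_obs, hits / total
    if mode == "approx":
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    raise GutcompassError(f"unknown mode '{mode}'")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise GutcompassError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DiversityResult:
    per_sample: pd.DataFrame   # sample, cohort, shannon
    per_cohort: pd.DataFrame   # cohort, n, median, q1, q3
    pairwise: pd.DataFrame     # cohort_a, cohort_b, statistic, p, q


def diversity_analysis(table: AbundanceTable, meta: SampleMetadata,
                       mode: str = "auto") -> DiversityResult:
    """Per-sample Shannon H plus all pairwise cohort rank-sum comparisons."""
    h = shannon_per_sample(table)
    cohorts = meta.column("cohort").reindex(h.index)
    per_sample = pd.DataFrame({"cohort": cohorts, "shannon": h})
    rows = []
    for cohort, grp in per_sample.groupby("cohort", sort=True):
        q1, med, q3 = np.percentile(grp["shannon"], [25, 50, 75])
        rows.append({"cohort": cohort, "n": len(grp), "median": med,
                     "q1": q1, "q3": q3})
    per_cohort = pd.DataFrame(rows)
    pairs = list(itertools.combinations(sorted(cohorts.unique()), 2))
    stats_rows = []
    for a, b in pairs:
        xa = per_sample.loc[per_sample["cohort"] == a, "shannon"].to_numpy()
        xb = per_sample.loc[per_sample["cohort"] == b, "shannon"].to_numpy()
        u, p = wilcoxon_rank_sum(xa, xb, mode=mode)
        stats_rows.append({"cohort_a": a, "cohort_b": b, "statistic": u, "p": p})
    pairwise = pd.DataFrame(stats_rows)
    if len(pairwise):
        pairwise["q"] = bh_adjust(pairwise["p"].to_numpy())
    return DiversityResult(per_sample=per_sample, per_cohort=per_cohort,
                           pairwise=pairwise)
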