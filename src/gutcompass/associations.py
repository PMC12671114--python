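"""Two-step medication-taxon association regression and biserial bootstrap.

Step one screens every (feature, medication) pair with a univariate
Gaussian linear model of the clr-transformed feature on the 0/1 exposure
flag, applying one Benjamini-Hochberg correction jointly across all pairs.
Step two fits, per feature, a single multivariate Gaussian model containing
every medication that survived screening for that feature plus age and sex,
reporting unadjusted two-sided p-values (the screening step already paid
the multiplicity price).  A separate utility bootstraps the point-biserial
correlation between a feature and a binary outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .diversity import bh_adjust
from .io import GutcompassError, SampleMetadata
from .transforms import TransformedMatrix

logger = logging.getLogger("gutcompass")

__all__ = [
    "univariate_screen",
    "multivariate_fit",
    "association_pipeline",
    "AssociationTable",
    "biserial_bootstrap",
    "BiserialResult",
]


def univariate_screen(features: TransformedMatrix, covariates: pd.DataFrame,
                      q_threshold: float = 0.05) -> pd.DataFrame:
    """Univariate linear screen of each feature against each 0/1 covariate.

    Returns one row per (feature, covariate) with slope, raw p, joint BH q,
    and the pass flag q < ``q_threshold``.  Constant features are skipped
    with a warning; covariates must have both levels present.
    """
    if features.transform_tag not in ("clr", "functional"):
        raise GutcompassError(
            f"association screening expects clr (or functional) features, "
            f"got '{features.transform_tag}'"
        )
    ymat = features.values
    n = ymat.shape[0]
    feat_names = np.array(features.feature_labels)
    sd = ymat.std(axis=0, ddof=1)
    keep = sd > 0
    skipped = feat_names[~keep]
    if skipped.size:
        logger.warning("skipping %d constant features in screening", skipped.size)
    rows = []
    for cov in covariates.columns:
        x = pd.to_numeric(covariates[cov]).to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise GutcompassError(f"covariate '{cov}' has a single level")
        xc = x - x.mean()
        sxx = float((xc ** 2).sum())
        y = ymat[:, keep]
        yc = y - y.mean(axis=0, keepdims=True)
        slope = (xc @ yc) / sxx
        rss = (yc ** 2).sum(axis=0) - slope ** 2 * sxx
        dof = n - 2
        se = np.sqrt(np.maximum(rss, 0.0) / dof / sxx)
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = np.where(se > 0, slope / se, np.inf * np.sign(slope))
        p = 2.0 * stats.t.sf(np.abs(tval), dof)
        for fname, b, pv in zip(feat_names[keep], slope, p):
            rows.append({"feature": fname, "covariate": cov,
                         "uni_effect": float(b), "uni_p": float(pv)})
    table = pd.DataFrame(rows)
    table["uni_q"] = bh_adjust(table["uni_p"].to_numpy())
    table["screened"] = table["uni_q"] < q_threshold
    return table


def multivariate_fit(feature_values: np.ndarray, design: pd.DataFrame
                     ) -> pd.DataFrame:
    """Gaussian linear model of one feature on screened medications + age + sex.

    Perfectly collinear columns are dropped (flagged) before fitting; the
    returned frame has one row per retained covariate with effect and p.
    """
    cols, names, aliased = [], [], []
    n = len(design)
    basis = np.ones((n, 1)) / np.sqrt(n)
    for col in design.columns:
        vec = pd.to_numeric(design[col]).to_numpy(dtype=float)
        resid = vec - basis @ (basis.T @ vec)
        norm = np.linalg.norm(resid)
        if norm < 1e-8 * max(1.0, np.linalg.norm(vec)):
            aliased.append(col)
            continue
        basis = np.hstack([basis, (resid / norm)[:, None]])
        cols.append(vec)
        names.append(col)
    if aliased:
        logger.warning("aliased covariates dropped from multivariate model: %s",
                       aliased)
    X = sm.add_constant(np.column_stack(cols))
    fit = sm.OLS(np.asarray(feature_values, float), X).fit()
    return pd.DataFrame({
        "covariate": names,
        "multi_effect": fit.params[1:],
        "multi_p": fit.pvalues[1:],
        "aliased_dropped": [",".join(aliased)] * len(names),
    })


@dataclass
class AssociationTable:
    univariate: pd.DataFrame   # feature, covariate, uni_effect, uni_p, uni_q, screened
    multivariate: pd.DataFrame  # feature, covariate, multi_effect, multi_p, is_medication
    q_threshold: float

    def heatmap_table(self, p_threshold: float = 0.05,
                      min_significant: int = 2) -> pd.DataFrame:
        """Features with >= ``min_significant`` significant multivariate
        associations, wide format (features x covariates, effect sizes)."""
        med = self.multivariate[self.multivariate["is_medication"]]
        sig_counts = (med[med["multi_p"] < p_threshold]
                      .groupby("feature").size())
        keep = sig_counts[sig_counts >= min_significant].index
        sub = med[med["feature"].isin(keep)]
        return sub.pivot(index="feature", columns="covariate",
                         values="multi_effect")


def association_pipeline(features: TransformedMatrix, meta: SampleMetadata,
                         q_threshold: float = 0.05) -> AssociationTable:
    """Run the two-step screen-then-adjust association analysis.

    Gating invariant: a (feature, medication) pair reaches the multivariate
    stage only if its univariate BH q is below ``q_threshold``; every
    multivariate model additionally contains age and sex.
    """
    med_cols = [c for c in meta.medication_columns
                if meta.column(c).reindex(features.sample_ids).nunique() > 1]
    if not med_cols:
        raise GutcompassError("no medication flag with both levels present")
    covs = meta.data.loc[features.sample_ids, med_cols]
    uni = univariate_screen(features, covs, q_threshold=q_threshold)
    screened = uni[uni["screened"]]
    multi_rows = []
    sex = meta.column("sex").reindex(features.sample_ids)
    sex_num = pd.to_numeric(sex, errors="coerce")
    if sex_num.isna().any():
        sex_num = (sex.astype(str) == sorted(sex.astype(str).unique())[-1]).astype(float)
    base = pd.DataFrame({
        "age": pd.to_numeric(meta.column("age").reindex(features.sample_ids)),
        "sex": sex_num,
    }, index=features.sample_ids)
    fdata = features.data
    for feature, grp in screened.groupby("feature", sort=True):
        meds = sorted(grp["covariate"])
        design = pd.concat([covs[meds], base], axis=1)
        res = multivariate_fit(fdata[feature].to_numpy(), design)
        res.insert(0, "feature", feature)
        res["is_medication"] = res["covariate"].isin(meds)
        multi_rows.append(res)
    multi = (pd.concat(multi_rows, ignore_index=True) if multi_rows
             else pd.DataFrame(columns=["feature", "covariate", "multi_effect",
                                        "multi_p", "aliased_dropped",
                                        "is_medication"]))
    # gating invariant, asserted on every run
    allowed = set(map(tuple, screened[["feature", "covariate"]].to_numpy()))
    med_pairs = set(map(tuple,
                        multi.loc[multi["is_medication"],
                                  ["feature", "covariate"]].to_numpy()))
    assert med_pairs <= allowed, "multivariate output contains unscreened pair"
    return AssociationTable(univariate=uni, multivariate=multi,
                            q_threshold=q_threshold)


@dataclass
class BiserialResult:
    r: float
    boot_mean: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_redraws: int


def biserial_bootstrap(values, outcome, n_boot: int = 1000, seed: int = 0,
                       max_redraws: int = 10000) -> BiserialResult:
    """Point-biserial correlation with a percentile bootstrap interval.

    The point-biserial r is the Pearson correlation of the values against
    the 0/1 outcome; ``n_boot`` resamples with replacement give the
    percentile 95% interval.  Resamples containing a single outcome class
    are redrawn (counted, capped at ``max_redraws`` total).
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) != 2:
        raise GutcompassError("outcome must have exactly two classes")
    r = float(stats.pointbiserialr(y, x).correlation)
    rng = np.random.default_rng(seed)
    n = len(x)
    boots = np.empty(n_boot)
    redraws = 0
    for i in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2 and np.ptp(x[idx]) > 0:
                break
            redraws += 1
            if redraws > max_redraws:
                raise GutcompassError("too many degenerate bootstrap resamples")
        boots[i] = stats.pearsonr(x[idx], y[idx]).statistic
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return BiserialResult(r=r, boot_mean=float(boots.mean()),
                          ci_low=float(lo), ci_high=float(hi),
                          n_boot=n_boot, n_redraws=redraws)
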