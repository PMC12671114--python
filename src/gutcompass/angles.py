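"""Cohort-centroid angular similarity in screened PCA space.

The idea: fit a PCA on square-root-transformed, autoscaled species
abundances; screen components with univariate logistic regressions against
a binary reference-cohort indicator (reference vs all others, P < alpha);
represent each cohort by the mean score vector of its samples on the
significant components; and summarize between-cohort similarity as the
angle between centroid vectors, with the reference cohort defining the 0
degree axis.  Uncertainty comes from a stratified nonparametric bootstrap:
samples are resampled with replacement within each cohort over ``n_iter``
iterations while the PCA and the screened subspace stay fixed, so angles
remain commensurable across iterations; an option refits the PCA per
iteration for sensitivity analysis.

Mean angles map onto interpretation bands: below 60 degrees, similar
composition; 60-120, dissimilar/uncorrelated (orthogonal near 90); above
120, inversely correlated.  Band edges are conventional and configurable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import GutcompassError, SampleMetadata
from .transforms import TransformedMatrix

logger = logging.getLogger("gutcompass")

__all__ = [
    "PCAModel",
    "pca_fit",
    "screen_pcs",
    "cohort_centroid",
    "angle_between",
    "AngularResult",
    "bootstrap_angles",
    "DEFAULT_BANDS",
]

#: (lower, upper, label); upper edge of the last band is inclusive
DEFAULT_BANDS = (
    (0.0, 60.0, "similar composition"),
    (60.0, 120.0, "dissimilar composition"),
    (120.0, 180.0, "inversely correlated"),
)

MIN_COHORT_SIZE = 3


@dataclass
class PCAModel:
    loadings: pd.DataFrame            # features x components, orthonormal cols
    scores: pd.DataFrame              # samples x components
    explained_variance: np.ndarray    # per component (n-1 denominator)
    center: np.ndarray                # feature means removed before SVD

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca_fit(X: TransformedMatrix) -> PCAModel:
    """Full singular-value decomposition PCA of an autoscaled matrix.

    Components are ordered by decreasing variance with a deterministic sign
    convention: each loading column's largest-magnitude entry is positive.
    """
    X.require_tag("sqrt_autoscaled")
    vals = X.values
    center = vals.mean(axis=0)
    xc = vals - center  # autoscaled input is already centered; cheap no-op
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # drop numerically null components
    tol = max(xc.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    keep = s > tol
    u, s, vt = u[:, keep], s[keep], vt[keep]
    for j in range(vt.shape[0]):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    scores = u * s
    comp_names = [f"PC{j + 1}" for j in range(len(s))]
    n = vals.shape[0]
    return PCAModel(
        loadings=pd.DataFrame(vt.T, index=X.feature_labels, columns=comp_names),
        scores=pd.DataFrame(scores, index=X.sample_ids, columns=comp_names),
        explained_variance=s ** 2 / (n - 1),
        center=center,
    )


def screen_pcs(model: PCAModel, outcome, alpha: float = 0.05
               ) -> tuple[list[str], pd.DataFrame]:
    """Univariate logistic screen of each PC against a binary outcome.

    Per component a logistic model (intercept + that component's scores) is
    fitted; components with two-sided Wald P < alpha are kept.  If a fit
    does not converge or separates perfectly, the likelihood-ratio p is used
    instead and the component is flagged.
    """
    y = np.asarray(outcome, dtype=float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise GutcompassError("screening outcome has a single class")
    rows = []
    kept = []
    for name in model.scores.columns:
        x = sm.add_constant(model.scores[name].to_numpy())
        coef = np.nan
        flagged = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, x).fit(disp=0, maxiter=100)
            converged = bool(fit.mle_retvals.get("converged", False))
            coef = float(fit.params[1])
            p = float(fit.pvalues[1])
            # (quasi-)separation saturates the coefficient and collapses the
            # Wald statistic (Hauck-Donner); fall back to the LRT then
            saturated = abs(coef) * float(np.std(x[:, 1])) > 15.0
            if not converged or not np.isfinite(p) or saturated:
                raise RuntimeError("non-convergence or separation")
        except Exception:
            flagged = True
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, x).fit(method="bfgs", disp=0, maxiter=500)
            coef = float(fit.params[1])
            llr = 2.0 * (fit.llf - fit.llnull)
            p = float(stats.chi2.sf(max(llr, 0.0), df=1))
        rows.append({"component": name, "coefficient": coef, "p": p,
                     "flagged": flagged})
        if p < alpha:
            kept.append(name)
    table = pd.DataFrame(rows)
    if not kept:
        logger.warning("no principal components pass screening at alpha=%g", alpha)
    return kept, table


def cohort_centroid(scores: pd.DataFrame, cohorts: pd.Series,
                    min_size: int = MIN_COHORT_SIZE) -> pd.DataFrame:
    """Mean score vector per cohort, restricted to the given (screened) columns."""
    cohorts = cohorts.reindex(scores.index)
    counts = cohorts.value_counts()
    small = counts[counts < min_size]
    if len(small):
        raise GutcompassError(
            f"cohort(s) below minimum size {min_size}: {dict(small)}"
        )
    return scores.groupby(cohorts, sort=True).mean()


def angle_between(u, v, tolerance_scale: float = 1e-8) -> float:
    """Angle in degrees in [0, 180] between two centroid vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    tol = tolerance_scale * np.sqrt(u.size)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu <= tol or nv <= tol:
        raise GutcompassError("centroid indistinct from origin")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def interpret_angle(mean_angle: float, bands=DEFAULT_BANDS) -> str:
    for lo, hi, label in bands:
        if lo <= mean_angle < hi:
            return label
    return bands[-1][2]  # 180 falls in the last band (inclusive upper edge)


@dataclass
class AngularResult:
    reference_cohort: str
    significant_pcs: list[str]
    screening_table: pd.DataFrame
    iteration_angles: dict[tuple[str, str], np.ndarray]
    summary: pd.DataFrame = field(default=None)  # pair, mean, sd, interpretation
    n_iter: int = 0

    def angles_long(self) -> pd.DataFrame:
        rows = []
        for (a, b), arr in self.iteration_angles.items():
            for i, ang in enumerate(arr):
                rows.append({"cohort_a": a, "cohort_b": b,
                             "iteration": i, "angle": ang})
        return pd.DataFrame(rows)


def bootstrap_angles(X: TransformedMatrix, meta: SampleMetadata,
                     reference_cohort: str, n_iter: int = 500,
                     seed: int = 0, alpha: float = 0.05,
                     bands=DEFAULT_BANDS,
                     refit_pca_per_iteration: bool = False,
                     variance_weighted: bool = False,
                     max_redraws: int = 100) -> AngularResult:
    """Stratified bootstrap of cohort-centroid angles in screened PCA space.

    The PCA and the logistic screening are fitted once on the full data; each
    iteration resamples samples with replacement within each cohort and
    recomputes all pairwise centroid angles in the fixed screened subspace.
    An iteration that produces a near-zero centroid is redrawn (up to
    ``max_redraws`` times).  Summaries are the linear mean and SD per pair.
    """
    cohorts = meta.column("cohort").reindex(X.sample_ids)
    labels = sorted(cohorts.unique())
    if reference_cohort not in labels:
        raise GutcompassError(f"unknown reference cohort '{reference_cohort}'")
    counts = cohorts.value_counts()
    small = counts[counts < MIN_COHORT_SIZE]
    if len(small):
        raise GutcompassError(
            f"cohort(s) below minimum size {MIN_COHORT_SIZE}: {dict(small)}"
        )
    model = pca_fit(X)
    outcome = (cohorts == reference_cohort).astype(int).to_numpy()
    kept, screening = screen_pcs(model, outcome, alpha=alpha)
    if not kept:
        raise GutcompassError(
            f"no significant principal components at alpha={alpha}; "
            "angular analysis cannot run"
        )
    scores = model.scores[kept]
    if variance_weighted:
        w = np.sqrt(model.explained_variance[[int(k[2:]) - 1 for k in kept]])
        scores = scores * w
    rng = np.random.default_rng(seed)
    groups = {lab: np.flatnonzero((cohorts == lab).to_numpy()) for lab in labels}
    pairs = list(combinations(labels, 2))
    angles = {p: np.empty(n_iter) for p in pairs}
    base_vals = X.values
    for it in range(n_iter):
        for attempt in range(max_redraws + 1):
            idx = np.concatenate([rng.choice(g, size=len(g), replace=True)
                                  for g in groups.values()])
            if refit_pca_per_iteration:
                boot_tm = TransformedMatrix(
                    data=pd.DataFrame(base_vals[idx],
                                      columns=X.feature_labels),
                    transform_tag="sqrt_autoscaled",
                )
                boot_model = pca_fit(boot_tm)
                # align the refit subspace to the reference loadings by
                # matching signs (Procrustes-style) before projecting
                ref_load = model.loadings[kept].to_numpy()
                boot_load = boot_model.loadings.to_numpy()[:, :len(kept)]
                signs = np.sign(np.sum(ref_load * boot_load, axis=0))
                signs[signs == 0] = 1.0
                proj = (base_vals[idx] - boot_model.center) @ (boot_load * signs)
                it_scores = pd.DataFrame(proj, columns=kept)
            else:
                it_scores = scores.iloc[idx].reset_index(drop=True)
            boot_cohorts = pd.Series(
                np.concatenate([[lab] * len(g) for lab, g in groups.items()]),
            )
            try:
                cents = it_scores.groupby(boot_cohorts, sort=True).mean()
                result = {}
                for a, b in pairs:
                    result[(a, b)] = angle_between(cents.loc[a], cents.loc[b])
                break
            except GutcompassError:
                continue
        else:
            raise GutcompassError(
                f"bootstrap iteration {it}: centroid degenerate after "
                f"{max_redraws} redraws"
            )
        for p in pairs:
            angles[p][it] = result[p]
    rows = []
    for a, b in pairs:
        arr = angles[(a, b)]
        mean, sd = float(arr.mean()), float(arr.std(ddof=1))
        rows.append({"cohort_a": a, "cohort_b": b, "mean_angle": mean,
                     "sd_angle": sd, "interpretation": interpret_angle(mean, bands)})
    summary = pd.DataFrame(rows)
    return AngularResult(
        reference_cohort=reference_cohort,
        significant_pcs=kept,
        screening_table=screening,
        iteration_angles=angles,
        summary=summary,
        n_iter=n_iter,
    )
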