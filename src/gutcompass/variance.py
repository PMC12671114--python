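"""Variance partitioning: redundancy analysis, stepwise selection, PERMANOVA.

Redundancy analysis (RDA) regresses a column-centered multivariate response
(here clr abundances, optionally column-bound with autoscaled functional
profiles) on a design matrix and reports the explained share of total
variance, R^2 = tr(Yhat' Yhat) / tr(Yc' Yc), with the Ezekiel adjustment
adjR^2 = 1 - (1 - R^2)(n - 1)/(n - m - 1).  Marginal per-variable fits
quantify each covariate alone; forward stepwise selection with conditional
permutation tests (Freedman-Lane residual permutation) and a global-adjR^2
ceiling reproduces the vegan ``ordiR2step`` logic.  PERMANOVA partitions a
distance matrix via the Gower-centered inner-product matrix (Anderson's
formulation) and assesses the pseudo-F by free permutation of sample labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enterotypes import DistanceMatrix
from .io import GutcompassError
from .transforms import TransformedMatrix

logger = logging.getLogger("gutcompass")

__all__ = [
    "build_design",
    "rda",
    "RDAResult",
    "marginal_partition",
    "stepwise_rda",
    "permanova",
    "PermanovaResult",
]


def build_design(variables: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str]]:
    """Encode a variable frame as a numeric design (no intercept column).

    Categorical/object columns become treatment-coded dummies; numeric
    columns pass through.  Constant and aliased (linearly dependent) columns
    are dropped with a warning.  Returns (matrix, kept names, dropped names).
    """
    blocks, names = [], []
    for col in variables.columns:
        s = variables[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            dummies = pd.get_dummies(s.astype(str), prefix=col, drop_first=True)
            for dcol in dummies.columns:
                blocks.append(dummies[dcol].to_numpy(dtype=float))
                names.append(dcol)
        else:
            blocks.append(pd.to_numeric(s).to_numpy(dtype=float))
            names.append(col)
    dropped = []
    kept_cols, kept_names = [], []
    n = len(variables)
    basis = np.ones((n, 1)) / np.sqrt(n)  # intercept always in the span
    for vec, name in zip(blocks, names):
        if np.ptp(vec) == 0:
            dropped.append(name)
            logger.warning("design column '%s' is constant; dropped", name)
            continue
        resid = vec - basis @ (basis.T @ vec)
        norm = np.linalg.norm(resid)
        if norm < 1e-8 * max(1.0, np.linalg.norm(vec)):
            dropped.append(name)
            logger.warning("design column '%s' is aliased; dropped", name)
            continue
        basis = np.hstack([basis, (resid / norm)[:, None]])
        kept_cols.append(vec)
        kept_names.append(name)
    if not kept_cols:
        raise GutcompassError("design has no usable columns")
    return np.column_stack(kept_cols), kept_names, dropped


def _response_matrix(Y) -> np.ndarray:
    if isinstance(Y, TransformedMatrix):
        return Y.values
    if isinstance(Y, pd.DataFrame):
        return Y.to_numpy(dtype=float)
    return np.atleast_2d(np.asarray(Y, dtype=float).T).T


@dataclass
class RDAResult:
    response_tag: str
    n: int
    m: int                       # design rank excluding intercept
    r2: float
    adj_r2: float
    dropped: list[str] = field(default_factory=list)
    marginal: pd.DataFrame | None = None     # variable, r2, adj_r2
    stepwise: pd.DataFrame | None = None     # step, variable, adj_r2, p


def _hat(design_no_int: np.ndarray) -> tuple[np.ndarray, int]:
    """Hat matrix of [1 | X] and its rank."""
    n = design_no_int.shape[0]
    X = np.hstack([np.ones((n, 1)), design_no_int]) if design_no_int.size else np.ones((n, 1))
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    rank = int((diag > 1e-10 * max(1.0, diag.max())).sum())
    q = q[:, :rank]
    return q @ q.T, rank


def ezekiel_adjust(r2: float, n: int, m: int) -> float:
    if n - m - 1 <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def rda(Y, X: pd.DataFrame, response_tag: str = "clr") -> RDAResult:
    """Global redundancy analysis of response Y on explanatory frame X."""
    ymat = _response_matrix(Y)
    if isinstance(Y, TransformedMatrix):
        response_tag = Y.transform_tag
    n = ymat.shape[0]
    if len(X) != n:
        raise GutcompassError("response and design have different sample counts")
    design, names, dropped = build_design(X)
    yc = ymat - ymat.mean(axis=0, keepdims=True)
    total = float((yc ** 2).sum())
    if total == 0:
        raise GutcompassError("response matrix has zero variance")
    hat, rank = _hat(design)
    m = rank - 1
    if n <= m + 1:
        raise GutcompassError(f"need n > m + 1 (n={n}, design rank m={m})")
    fitted = hat @ yc
    r2 = float((fitted ** 2).sum()) / total
    return RDAResult(response_tag=response_tag, n=n, m=m, r2=r2,
                     adj_r2=ezekiel_adjust(r2, n, m), dropped=dropped)


def marginal_partition(Y, variables: pd.DataFrame,
                       response_tag: str = "clr") -> RDAResult:
    """One single-variable RDA per column, plus the joint all-variable model."""
    joint = rda(Y, variables, response_tag=response_tag)
    rows = []
    for col in variables.columns:
        try:
            single = rda(Y, variables[[col]], response_tag=response_tag)
            rows.append({"variable": col, "r2": single.r2,
                         "adj_r2": single.adj_r2})
        except GutcompassError as exc:
            logger.warning("marginal RDA for '%s' undefined: %s", col, exc)
            rows.append({"variable": col, "r2": np.nan, "adj_r2": np.nan})
    joint.marginal = pd.DataFrame(rows)
    return joint


def stepwise_rda(Y, candidates: pd.DataFrame, alpha: float = 0.05,
                 n_perm: int = 999, seed: int = 0,
                 response_tag: str = "clr") -> RDAResult:
    """Forward selection with permutation testing and a global-adjR^2 ceiling.

    At each step the candidate giving the largest adjusted-R^2 gain is
    tested by Freedman-Lane permutation of the current model's residuals;
    it is admitted only if its conditional p < alpha and the grown model's
    adjR^2 stays at or below the all-candidate global adjR^2.
    """
    ymat = _response_matrix(Y)
    if isinstance(Y, TransformedMatrix):
        response_tag = Y.transform_tag
    n = ymat.shape[0]
    yc = ymat - ymat.mean(axis=0, keepdims=True)
    total = float((yc ** 2).sum())
    global_adj = rda(yc, candidates, response_tag=response_tag).adj_r2
    rng = np.random.default_rng(seed)
    remaining = list(candidates.columns)
    selected: list[str] = []
    trace_rows = []
    current_adj = 0.0

    def fit_adj(cols: list[str]) -> tuple[float, np.ndarray, int]:
        if cols:
            design, _, _ = build_design(candidates[cols])
        else:
            design = np.empty((n, 0))
        hat, rank = _hat(design)
        r2 = float(((hat @ yc) ** 2).sum()) / total
        return ezekiel_adjust(r2, n, rank - 1), hat, rank

    _, hat_s, rank_s = fit_adj(selected)
    while remaining:
        scored = []
        for cand in remaining:
            try:
                adj_new, hat_f, rank_f = fit_adj(selected + [cand])
            except GutcompassError:
                continue
            if np.isfinite(adj_new):
                scored.append((adj_new, cand, hat_f, rank_f))
        if not scored:
            break
        scored.sort(key=lambda t: (-t[0], t[1]))
        adj_new, cand, hat_f, rank_f = scored[0]
        if adj_new <= current_adj or adj_new > global_adj + 1e-12:
            break
        df_c = rank_f - rank_s
        if df_c < 1:
            remaining.remove(cand)
            continue
        # Freedman-Lane: permute residuals of the current model
        resid = yc - hat_s @ yc
        g_r = resid @ resid.T
        tr_g = float(np.trace(g_r))
        t_f = float((hat_f * g_r).sum())
        t_s = float((hat_s * g_r).sum())
        denom_df = n - rank_f
        f_obs = ((t_f - t_s) / df_c) / ((tr_g - t_f) / denom_df)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            gp = g_r[np.ix_(perm, perm)]
            tf = float((hat_f * gp).sum())
            ts = float((hat_s * gp).sum())
            f = ((tf - ts) / df_c) / ((np.trace(gp) - tf) / denom_df)
            if f >= f_obs - 1e-12:
                hits += 1
        p = (1 + hits) / (1 + n_perm)
        if p >= alpha:
            break
        selected.append(cand)
        remaining.remove(cand)
        current_adj, hat_s, rank_s = adj_new, hat_f, rank_f
        trace_rows.append({"step": len(selected), "variable": cand,
                           "adj_r2": current_adj, "p": p})
    if selected:
        result = rda(yc, candidates[selected], response_tag=response_tag)
    else:
        result = RDAResult(response_tag=response_tag, n=n, m=0, r2=0.0,
                           adj_r2=0.0)
    result.stepwise = pd.DataFrame(
        trace_rows, columns=["step", "variable", "adj_r2", "p"]
    )
    return result


@dataclass
class PermanovaResult:
    pseudo_f: float
    partial_r2: float
    n_permutations: int
    p_value: float
    permuted_f_mean: float
    permuted_f_sd: float
    permuted_f_max: float


def permanova(D: DistanceMatrix, grouping, n_perm: int = 999,
              seed: int = 0) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    ``grouping`` may be a categorical vector (one-way design) or a DataFrame
    of explanatory columns.  The pseudo-F comes from the Gower-centered
    matrix G = J(-d^2/2)J: F = [tr(HG)/m] / [tr((I-H)G)/(n-m-1)].  The
    p-value uses the add-one rule over free row/column permutations of G.
    """
    d = D.values
    n = d.shape[0]
    if n_perm < 99:
        warnings.warn("n_perm < 99 gives a very coarse permutation p-value")
    if isinstance(grouping, pd.DataFrame):
        frame = grouping
    else:
        g = pd.Series(grouping)
        if g.nunique() < 2:
            raise GutcompassError("PERMANOVA needs at least 2 groups")
        counts = g.value_counts()
        if (counts < 2).any():
            raise GutcompassError(
                f"PERMANOVA groups need >= 2 samples: {dict(counts[counts < 2])}"
            )
        frame = pd.DataFrame({"group": g.astype(str).to_numpy()})
    design, _, _ = build_design(frame)
    hat, rank = _hat(design)
    m = rank - 1
    if m < 1:
        raise GutcompassError("PERMANOVA design explains nothing (rank 1)")
    if n - m - 1 <= 0:
        raise GutcompassError("too few samples for the design")
    a = -0.5 * d ** 2
    g_mat = a - a.mean(axis=0, keepdims=True) - a.mean(axis=1, keepdims=True) + a.mean()
    tr_g = float(np.trace(g_mat))
    t_h = float((hat * g_mat).sum())
    f_obs = (t_h / m) / ((tr_g - t_h) / (n - m - 1))
    rng = np.random.default_rng(seed)
    f_perm = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        gp = g_mat[np.ix_(perm, perm)]
        th = float((hat * gp).sum())
        f_perm[i] = (th / m) / ((tr_g - th) / (n - m - 1))
    p = (1 + int((f_perm >= f_obs - 1e-12).sum())) / (1 + n_perm)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        partial_r2=float(t_h / tr_g),
        n_permutations=n_perm,
        p_value=float(p),
        permuted_f_mean=float(f_perm.mean()),
        permuted_f_sd=float(f_perm.std(ddof=1)),
        permuted_f_max=float(f_perm.max()),
    )
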