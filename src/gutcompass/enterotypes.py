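"""Enterotype analysis: JSD distances, PAM clustering, CH model selection, PCoA.

The procedure follows the classic enterotyping recipe: square-root
Jensen-Shannon divergence between genus-level abundance profiles gives a
metric distance matrix; Partitioning Around Medoids (PAM) clusters it for a
range of k; the Calinski-Harabasz (CH) index — computed on principal
coordinates, which supply the centroids CH needs — scores each k.  The
pipeline records the full CH curve and accepts a user-forced k, since the
CH optimum is a guide, not a mandate (a study may prefer k matching its
cohort structure).

PAM is implemented here directly (BUILD + SWAP with strict-improvement
swaps and deterministic tie-breaking) because no installed library provides
k-medoids on a precomputed distance matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn import metrics as _skmetrics

from .io import AbundanceTable, GutcompassError

logger = logging.getLogger("gutcompass")

__all__ = [
    "DistanceMatrix",
    "jsd_distance",
    "bray_curtis_distance",
    "euclidean_distance",
    "pam",
    "calinski_harabasz",
    "pcoa",
    "EnterotypeResult",
    "enterotype_pipeline",
]

JSD_MAX = float(np.sqrt(np.log(2.0)))


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with zero diagonal."""

    sample_ids: list
    values: np.ndarray
    metric_tag: str  # {jsd, bray_curtis, euclidean_clr, euclidean}

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise GutcompassError("distance matrix must be square")
        if not np.allclose(d, d.T, atol=1e-12):
            raise GutcompassError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise GutcompassError("distance matrix must have zero diagonal")
        if (d < -1e-12).any():
            raise GutcompassError("distance matrix must be nonnegative")
        if self.metric_tag == "jsd" and (d > JSD_MAX + 1e-12).any():
            raise GutcompassError("jsd distances exceed sqrt(ln 2)")
        self.values = d

    @property
    def n(self) -> int:
        return self.values.shape[0]


def jsd_distance(table: AbundanceTable) -> DistanceMatrix:
    """Square-root Jensen-Shannon divergence (natural log) between samples.

    d(P, Q) = sqrt(H(M) - (H(P) + H(Q))/2) with M = (P+Q)/2; bounded by
    sqrt(ln 2) and a true metric.
    """
    props = table.proportions().to_numpy()
    d = squareform(pdist(props, metric="jensenshannon"))
    d = np.nan_to_num(d, nan=0.0)  # identical rows can give 0/0 -> 0
    np.fill_diagonal(d, 0.0)
    d = np.minimum(d, JSD_MAX)  # clip float noise at the theoretical bound
    return DistanceMatrix(list(table.data.index), (d + d.T) / 2.0, "jsd")


def bray_curtis_distance(table: AbundanceTable) -> DistanceMatrix:
    props = table.proportions().to_numpy()
    d = squareform(pdist(props, metric="braycurtis"))
    return DistanceMatrix(list(table.data.index), (d + d.T) / 2.0, "bray_curtis")


def euclidean_distance(values: pd.DataFrame, tag: str = "euclidean") -> DistanceMatrix:
    d = squareform(pdist(values.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix(list(values.index), (d + d.T) / 2.0, tag)


# ---------------------------------------------------------------------------
# PAM (k-medoids): BUILD + SWAP
# ---------------------------------------------------------------------------

def _assign(d: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    """Assign each point to its nearest medoid (ties -> lowest-index medoid)."""
    sub = d[:, medoids]                      # medoids kept in sorted order
    which = np.argmin(sub, axis=1)           # argmin takes the first tie
    cost = float(sub[np.arange(d.shape[0]), which].sum())
    return which, cost


def _build(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=0)))]
    d1 = d[:, medoids[0]].copy()
    for _ in range(1, k):
        gains = np.maximum(d1[:, None] - d, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        c = int(np.argmax(gains))
        medoids.append(c)
        d1 = np.minimum(d1, d[:, c])
    return np.sort(np.array(medoids))


def _swap(d: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """SWAP phase: apply the best strictly-improving swap until local optimum."""
    n = d.shape[0]
    medoids = np.sort(medoids.copy())
    _, cost = _assign(d, medoids)
    while True:
        sub = d[:, medoids]
        order = np.argsort(sub, axis=1, kind="stable")
        nearest = order[:, 0]
        d1 = sub[np.arange(n), nearest]
        d2 = sub[np.arange(n), order[:, 1]] if len(medoids) > 1 else np.full(n, np.inf)
        non_medoids = np.setdiff1d(np.arange(n), medoids)
        best_delta, best_pair = -1e-12, None
        for cand in non_medoids:
            dj = d[:, cand]
            base_term = np.minimum(dj - d1, 0.0)
            total_base = base_term.sum()
            # correction per removed medoid: points assigned to it re-home
            corr = np.minimum(dj, d2) - d1 - base_term
            per_out = np.bincount(nearest, weights=corr, minlength=len(medoids))
            deltas = total_base + per_out
            o = int(np.argmin(deltas))
            if deltas[o] < best_delta:
                best_delta, best_pair = float(deltas[o]), (o, int(cand))
        if best_pair is None:
            break
        o, cand = best_pair
        new_medoids = medoids.copy()
        new_medoids[o] = cand
        new_medoids = np.sort(new_medoids)
        _, new_cost = _assign(d, new_medoids)
        assert new_cost <= cost + 1e-9, "PAM swap increased cost"
        medoids, cost = new_medoids, new_cost
    assign, cost = _assign(d, medoids)
    return medoids, assign, cost


def pam(D: DistanceMatrix | np.ndarray, k: int, restarts: int = 10,
        seed: int | np.random.Generator | None = 0) -> tuple[np.ndarray, np.ndarray, float]:
    """Partitioning Around Medoids on a precomputed distance matrix.

    Restart 0 uses the deterministic BUILD initialization; further restarts
    draw random initial medoids.  Returns (medoid indices sorted ascending,
    assignment of each point to a medoid position, total cost) of the best
    local optimum found.
    """
    d = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    n = d.shape[0]
    if not 2 <= k < n:
        raise GutcompassError(f"need 2 <= k < n, got k={k}, n={n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    best = None
    for r in range(max(1, restarts)):
        init = _build(d, k) if r == 0 else np.sort(rng.choice(n, size=k, replace=False))
        medoids, assign, cost = _swap(d, init)
        if best is None or cost < best[2] - 1e-12:
            best = (medoids, assign, cost)
    return best


def calinski_harabasz(coords: np.ndarray, labels: np.ndarray) -> float:
    """CH index = [B/(k-1)] / [W/(n-k)] on embedded coordinates."""
    labels = np.asarray(labels)
    n = len(labels)
    k = len(np.unique(labels))
    if k < 2:
        raise GutcompassError("CH needs at least 2 clusters")
    if k >= n:
        raise GutcompassError("CH undefined for singleton-only clustering (k = n)")
    return float(_skmetrics.calinski_harabasz_score(np.asarray(coords, float), labels))


def pcoa(D: DistanceMatrix, m: int | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical scaling (principal coordinates) of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, and returns coordinates on the
    positive-eigenvalue axes scaled by sqrt(eigenvalue).  All eigenvalues
    (including negative ones, reported unaltered) come back sorted
    descending.
    """
    d = D.values
    n = d.shape[0]
    b = -0.5 * d ** 2
    b = b - b.mean(axis=0, keepdims=True) - b.mean(axis=1, keepdims=True) + b.mean()
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-10, 1e-10 * abs(eigval).max()) if n else 0.0
    npos = int((eigval > tol).sum())
    if m is None:
        m = npos
    if m > npos:
        warnings.warn(
            f"requested {m} axes but only {npos} positive eigenvalues; truncating"
        )
        m = npos
    coords = eigvec[:, :m] * np.sqrt(eigval[:m])
    # deterministic sign: largest-magnitude coordinate positive per axis
    for j in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    frame = pd.DataFrame(coords, index=D.sample_ids,
                         columns=[f"PCo{j + 1}" for j in range(m)])
    return frame, eigval


@dataclass
class EnterotypeResult:
    chosen_k: int
    assignments: pd.Series          # sample -> cluster label (1-based ints)
    medoid_ids: list
    ch_by_k: dict[int, float]
    top_genera: pd.DataFrame        # cluster, rank, genus, median_abundance
    pcoa_coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    forced_k: bool = False


def enterotype_pipeline(table: AbundanceTable, k_range=range(2, 7),
                        restarts: int = 10, seed: int = 0,
                        force_k: int | None = None,
                        top_n_genera: int = 5) -> EnterotypeResult:
    """Full enterotyping of a genus-level table.

    JSD distances -> PAM for each k in ``k_range`` -> CH index per k on PCoA
    coordinates -> chosen k maximizes CH (ties to the smaller k) unless
    ``force_k`` overrides the choice.  Per-cluster driver genera are the top
    ``top_n_genera`` by median relative abundance.
    """
    if table.rank not in ("genus", "functional"):
        logger.warning("enterotyping is conventionally run at genus rank, got %s",
                       table.rank)
    D = jsd_distance(table)
    n = D.n
    k_range = [k for k in k_range if 2 <= k < n]
    if not k_range:
        raise GutcompassError("no valid k in requested range")
    coords_all, eigval = pcoa(D)
    rng = np.random.default_rng(seed)
    ch_by_k: dict[int, float] = {}
    runs: dict[int, tuple] = {}
    for k in k_range:
        medoids, assign, cost = pam(D, k, restarts=restarts, seed=rng)
        runs[k] = (medoids, assign, cost)
        ch_by_k[k] = calinski_harabasz(coords_all.to_numpy(), assign)
    chosen_k = max(sorted(ch_by_k), key=lambda k: (ch_by_k[k], -k))
    use_k = force_k if force_k is not None else chosen_k
    if use_k not in runs:
        medoids, assign, cost = pam(D, use_k, restarts=restarts, seed=rng)
        runs[use_k] = (medoids, assign, cost)
    medoids, assign, _ = runs[use_k]
    assignments = pd.Series(assign + 1, index=table.data.index, name="cluster")
    rows = []
    for cluster in range(use_k):
        members = table.data.loc[assignments == cluster + 1]
        medians = members.median(axis=0).sort_values(ascending=False)
        for rank_i, (genus, med) in enumerate(medians.head(top_n_genera).items(), 1):
            rows.append({"cluster": cluster + 1, "rank": rank_i,
                         "genus": genus, "median_abundance": float(med)})
    quality = eigval[eigval > 0].sum() / np.abs(eigval).sum()
    logger.info("PCoA positive-eigenvalue mass fraction: %.3f", quality)
    return EnterotypeResult(
        chosen_k=chosen_k,
        assignments=assignments,
        medoid_ids=[table.data.index[i] for i in medoids],
        ch_by_k=ch_by_k,
        top_genera=pd.DataFrame(rows),
        pcoa_coordinates=coords_all.iloc[:, : min(10, coords_all.shape[1])],
        eigenvalues=eigval,
        forced_k=force_k is not None,
    )
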