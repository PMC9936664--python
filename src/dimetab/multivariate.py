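"""Multivariate statistics: sample-sample distances, PERMANOVA, non-metric
multidimensional scaling and PCA summaries.

PERMANOVA partitions the total sum of squared inter-sample distances into
contributions of the grouping variables using Anderson's formulation: the
distance matrix is Gower-centered into an inner-product matrix G, each
term's sum of squares is the trace of the projection of G onto the span of
its design-matrix columns (sequential, Type-I, in the order the grouping
variables are given), and the pseudo-F statistic is calibrated by freely
permuting samples.

NMDS minimizes Kruskal's stress-1

    stress = sqrt( Σ (d_ij − dhat_ij)² / Σ d_ij² )

over k-dimensional configurations, where dhat is the monotone (isotonic)
regression of the configuration distances on the rank order of the input
dissimilarities; optimization is SMACOF (Guttman transform) alternated
with isotonic regression, best of several random restarts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.isotonic import isotonic_regression

from .errors import ValidationError
from .preprocessing import IntensityMatrix, has_formula

#: which distance each normalization method maps to: signed outputs need
#: euclidean; non-negative outputs use Bray-Curtis. Jaccard by explicit flag.
DISTANCE_FOR_NORMALIZATION = {
    "max": "bray_curtis",
    "minmax": "bray_curtis",
    "sum": "bray_curtis",
    "mean": "euclidean",
    "median": "euclidean",
    "zscore": "euclidean",
    "raw": "bray_curtis",
}


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    metric: str
    values: np.ndarray  # square symmetric, zero diagonal

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def compute_distance(matrix: IntensityMatrix, metric: str | None = None) -> DistanceMatrix:
    """Sample-sample distances from a (normalized) intensity matrix.

    ``metric`` defaults to the mapping from the matrix's normalization
    method (Bray-Curtis for non-negative outputs, Euclidean for signed
    ones); Jaccard operates on presence/absence.
    """
    if metric is None:
        metric = DISTANCE_FOR_NORMALIZATION[matrix.normalization]
    X = matrix.values.to_numpy(float).T  # samples × peaks
    if metric == "bray_curtis":
        if (X < 0).any():
            raise ValidationError(
                "Bray-Curtis requires non-negative values; this normalization "
                "produces signed output — use the euclidean metric"
            )
        cond = pdist(X, metric="braycurtis")
    elif metric == "euclidean":
        cond = pdist(X, metric="euclidean")
    elif metric == "jaccard":
        cond = pdist(X > 0, metric="jaccard")
    else:
        raise ValidationError(f"unknown distance metric {metric!r}")
    return DistanceMatrix(matrix.sample_ids, metric, squareform(cond))


# ---------------------------------------------------------------------------
# PERMANOVA

def _gower_center(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


def _design_matrices(
    metadata: pd.DataFrame, sample_ids: list[str], grouping: list[str]
) -> tuple[list[str], list[np.ndarray], list[int]]:
    """Sequential term names, cumulative design matrices and term dfs."""
    dummies = {}
    for g in grouping:
        d = pd.get_dummies(metadata.loc[sample_ids, g], dtype=float).to_numpy()
        dummies[g] = d
    n = len(sample_ids)
    intercept = np.ones((n, 1))
    terms, cum, dfs = [], [], []
    X = intercept
    rank_prev = 1
    parts: list[np.ndarray] = []
    if len(grouping) == 1:
        parts = [(grouping[0], dummies[grouping[0]])]
    else:
        a, b = grouping
        inter = np.einsum("ij,ik->ijk", dummies[a], dummies[b]).reshape(n, -1)
        parts = [(a, dummies[a]), (b, dummies[b]), (f"{a}:{b}", inter)]
    for name, block in parts:
        X = np.hstack([X, block])
        rank = np.linalg.matrix_rank(X)
        terms.append(name)
        cum.append(X)
        dfs.append(rank - rank_prev)
        rank_prev = rank
    return terms, cum, dfs


def permanova(
    dist: DistanceMatrix,
    metadata: pd.DataFrame,
    grouping: list[str] | str,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutational multivariate ANOVA on a distance matrix.

    One-way for a single grouping variable; two-way with interaction
    (sequential, Type-I sums of squares) for two. Returns the usual
    PERMANOVA table: df, sum of squares, R², pseudo-F and the permutation
    p-value ``(1 + #{F* >= F}) / (1 + n_perm)`` per term.
    """
    if isinstance(grouping, str):
        grouping = [grouping]
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    ids = dist.sample_ids
    for g in grouping:
        counts = metadata.loc[ids, g].value_counts()
        if len(counts) < 2 or (counts < 2).any():
            raise ValidationError(
                f"grouping {g!r} needs >= 2 groups with >= 2 samples each"
            )
    D = dist.values
    if not D.any():
        raise ValidationError("degenerate all-zero distance matrix")
    G = _gower_center(D)
    n = len(ids)
    terms, cum, dfs = _design_matrices(metadata, ids, grouping)
    hats = [_hat(X) for X in cum]
    ss_total = float(np.trace(G))
    df_res = n - np.linalg.matrix_rank(cum[-1])

    def term_stats(Gp: np.ndarray) -> tuple[np.ndarray, float]:
        tr = np.array([float(np.trace(H @ Gp)) for H in hats])
        ss = np.diff(np.concatenate([[0.0], tr]))
        ss_res = float(np.trace(Gp)) - tr[-1]
        return ss, ss_res

    ss_obs, ss_res_obs = term_stats(G)
    ms_res = ss_res_obs / df_res
    F_obs = (ss_obs / np.array(dfs)) / ms_res

    # the permutation distribution is over distinct label assignments: a
    # permutation that merely reproduces the observed partition (e.g. a
    # wholesale group swap in a balanced one-way design) yields the same F
    # by symmetry and carries no information — the observed assignment
    # already contributes the "+1" — so such draws are rejected and redrawn
    labels = np.array(
        list(zip(*(metadata.loc[ids, g].to_numpy() for g in grouping)))
    )

    def _canonical(lab: np.ndarray) -> tuple:
        seen: dict = {}
        return tuple(seen.setdefault(tuple(l), len(seen)) for l in lab)

    observed_partition = _canonical(labels)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        while _canonical(labels[perm]) == observed_partition:
            perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        ss_p, ss_res_p = term_stats(Gp)
        F_p = (ss_p / np.array(dfs)) / (ss_res_p / df_res)
        exceed += F_p >= F_obs
    p = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for i, name in enumerate(terms):
        rows.append(
            {
                "term": name,
                "df": dfs[i],
                "sum_sq": ss_obs[i],
                "R2": ss_obs[i] / ss_total,
                "pseudo_F": F_obs[i],
                "p_perm": p[i],
            }
        )
    rows.append(
        {
            "term": "Residual",
            "df": df_res,
            "sum_sq": ss_res_obs,
            "R2": ss_res_obs / ss_total,
            "pseudo_F": np.nan,
            "p_perm": np.nan,
        }
    )
    rows.append(
        {
            "term": "Total",
            "df": n - 1,
            "sum_sq": ss_total,
            "R2": 1.0,
            "pseudo_F": np.nan,
            "p_perm": np.nan,
        }
    )
    table = pd.DataFrame(rows)
    table.attrs["n_permutations"] = n_perm
    return table


# ---------------------------------------------------------------------------
# NMDS

@dataclass
class OrdinationResult:
    method: str
    scores: pd.DataFrame                      # samples × axes
    stress: float | None = None               # NMDS
    stress_history: list[float] = field(default_factory=list)
    explained_variance: np.ndarray | None = None  # PCA
    loadings: pd.DataFrame | None = None          # PCA
    converged: bool = True


def _nmds_single(
    d: np.ndarray, n: int, k: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, float, list[float], bool]:
    order = np.argsort(d, kind="stable")
    X = rng.standard_normal((n, k))
    history: list[float] = []
    converged = False
    prev = np.inf
    for _ in range(max_iter):
        dist = pdist(X)
        dhat = np.empty_like(dist)
        dhat[order] = isotonic_regression(dist[order])
        denom = float(dist @ dist)
        stress = np.sqrt(float((dist - dhat) @ (dist - dhat)) / denom) if denom else 0.0
        if stress > prev - tol:
            if stress <= prev:
                history.append(stress)
                prev = stress
            converged = True
            break
        history.append(stress)
        prev = stress
        # Guttman transform toward the monotone-regressed targets
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, dhat / dist, 0.0)
        B = -squareform(ratio)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = B @ X / n
    return X, prev, history, converged


def nmds(
    dist: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric multidimensional scaling by SMACOF + isotonic regression.

    Runs ``n_restarts`` random starts and keeps the configuration with the
    lowest final stress-1. Scores are centered and rotated to principal
    axes. ``converged=False`` flags that no restart met the tolerance.
    """
    n = len(dist.sample_ids)
    if n < k + 2:
        raise ValidationError(f"NMDS with k={k} needs at least {k + 2} samples")
    d = squareform(dist.values, checks=False)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        X, stress, history, conv = _nmds_single(d, n, k, rng, max_iter, tol)
        if best is None or stress < best[1]:
            best = (X, stress, history, conv)
    X, stress, history, conv = best
    if not conv:
        warnings.warn("NMDS did not converge in any restart; returning best", stacklevel=2)
    X = X - X.mean(axis=0)
    # rotate to principal axes for a reproducible orientation
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    X = X @ Vt.T
    scores = pd.DataFrame(
        X, index=dist.sample_ids, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return OrdinationResult(
        "NMDS", scores, stress=stress, stress_history=history, converged=conv
    )


# ---------------------------------------------------------------------------
# PCA summaries

def _pca(table: pd.DataFrame, method_label: str) -> OrdinationResult:
    X = table.copy()
    # tolerance-based: summation round-off can leave a ~1-ulp "variance"
    # on columns that are constant by construction
    sd = X.std(ddof=0)
    const = X.columns[sd <= 1e-12 * np.maximum(1.0, X.mean().abs())]
    if len(const):
        warnings.warn(f"dropping constant variables: {list(const)}", stacklevel=3)
        X = X.drop(columns=const)
    if X.shape[1] == 0:
        # identical samples: no variance anywhere; all scores 0 after centering
        scores = pd.DataFrame(0.0, index=table.index, columns=["PC1"])
        return OrdinationResult(
            method_label, scores, explained_variance=np.array([0.0]),
            loadings=pd.DataFrame(index=table.columns, columns=["PC1"], dtype=float),
        )
    Z = (X - X.mean()) / X.std(ddof=0)
    pca = PCA()
    scores = pca.fit_transform(Z.to_numpy())
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return OrdinationResult(
        method_label,
        pd.DataFrame(scores, index=table.index, columns=cols),
        explained_variance=pca.explained_variance_ratio_,
        loadings=pd.DataFrame(pca.components_.T, index=X.columns, columns=cols),
    )


def class_composition_per_sample(
    peaks: pd.DataFrame, matrix: IntensityMatrix
) -> pd.DataFrame:
    """Per-sample percentage of detected formula-bearing peaks in each
    compound class."""
    hf = has_formula(peaks)
    rows = {}
    for s in matrix.sample_ids:
        det = peaks.loc[hf & (peaks[s] > 0), "compound_class"]
        counts = det.value_counts()
        rows[s] = 100.0 * counts / counts.sum() if counts.sum() else counts
    return pd.DataFrame(rows).fillna(0.0).T.sort_index(axis=1)


def magnitude_averaged_indices(
    peaks: pd.DataFrame,
    matrix: IntensityMatrix,
    indices: tuple[str, ...] = ("nosc", "gfe", "ai_mod", "dbe"),
) -> pd.DataFrame:
    """Per-sample intensity-weighted mean of each index over the detected,
    formula-bearing peaks: Σ(I_i · index_i) / Σ I_i."""
    if matrix.normalization != "raw":
        raise ValidationError("magnitude-averaged indices use raw intensities as weights")
    hf = has_formula(peaks).reindex(matrix.values.index, fill_value=False)
    rows = {}
    for s in matrix.sample_ids:
        col = matrix.values[s]
        w = col[(col > 0) & hf]
        idx_vals = peaks.loc[w.index, list(indices)]
        rows[s] = (idx_vals.mul(w, axis=0).sum() / w.sum()).to_dict()
    return pd.DataFrame(rows).T[list(indices)]


def pca_summaries(
    peaks: pd.DataFrame, matrix: IntensityMatrix
) -> tuple[OrdinationResult, OrdinationResult]:
    """Two standard PCA views of the sample set: (1) compound-class
    composition percentages, (2) magnitude-averaged thermodynamic indices.
    Variables are standardized to zero mean/unit variance first."""
    if len(matrix.sample_ids) < 3:
        raise ValidationError("PCA summaries need at least 3 samples")
    comp = class_composition_per_sample(peaks, matrix)
    mag = magnitude_averaged_indices(peaks, matrix)
    return _pca(comp, "PCA_composition"), _pca(mag, "PCA_indices")
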