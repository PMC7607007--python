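"""Feature standardization, Ward clustering with silhouette model selection,
and the cohort-level statistical comparisons.

Neurons are clustered on their standardized 13-parameter morphometric
vectors: each column is centered to mean 0 and scaled to unit standard
deviation (n-1 denominator), a Euclidean dissimilarity matrix is formed, and
agglomerative hierarchical clustering with Ward's linkage is applied.  The
number of clusters is chosen by the average-silhouette criterion over a small
k range (ties toward the smaller k; singleton clusters score 0 by
convention).

Two Ward variants are exposed: the proper Ward criterion on Euclidean
distances (the textbook form, equivalent to R's ``ward.D2``; default) and the
``ward.D`` form that runs the Lance-Williams recurrence on unsquared
distances.  The ``ward.D`` path is an in-package Lance-Williams
implementation, which doubles as an independent cross-check of the default
path when fed squared distances.

Statistical comparisons mirror the cohort analyses: a Pearson correlation of
terminal counts, a single-predictor regression trend test (ANOVA F on the
regression, with optional exclusion of the Rohon-Beard population), and an
axial-vs-fin total length comparison run as the printed chi-square
goodness-of-fit of the two summed lengths against equal expectation —
statistically unusual for continuous totals, so a paired Wilcoxon signed-rank
alternative is reported alongside, both clearly labeled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.metrics import silhouette_score

__all__ = [
    "Standardizer",
    "ClusterAssignment",
    "standardize",
    "ward_cluster",
    "silhouette_select_k",
    "dendrogram_to_newick",
    "correlation_terminals",
    "trend_test",
    "length_comparison",
    "leave_one_feature_out",
]

DEFAULT_K_MAX = 8


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass
class Standardizer:
    """Per-column location/scale of a feature matrix (for the inverse map)."""

    columns: list[str]
    means: np.ndarray
    stds: np.ndarray
    imputed: dict[str, int] = field(default_factory=dict)

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        return (df[self.columns] - self.means) / self.stds

    def inverse_transform(self, z: pd.DataFrame) -> pd.DataFrame:
        return z[self.columns] * self.stds + self.means


def standardize(df: pd.DataFrame) -> tuple[pd.DataFrame, Standardizer]:
    """Scale each column to mean 0 and standard deviation 1 (n-1 denominator).

    NaN sentinel cells (metrics undefined on a given neuron) are imputed with
    the column mean first, with a warning naming the columns.  A constant
    column cannot be scaled and raises ``ValueError`` naming it.
    """
    if len(df) < 2:
        raise ValueError("standardization needs at least 2 rows")
    work = df.astype(float).copy()
    imputed: dict[str, int] = {}
    for col in work.columns:
        n_nan = int(work[col].isna().sum())
        if n_nan:
            if n_nan == len(work):
                raise ValueError(f"column {col!r} is entirely NaN")
            work[col] = work[col].fillna(work[col].mean())
            imputed[col] = n_nan
    if imputed:
        warnings.warn(f"mean-imputed NaN sentinels in columns: {imputed}")
    means = work.mean(axis=0).to_numpy()
    stds = work.std(axis=0, ddof=1).to_numpy()
    for col, s in zip(work.columns, stds):
        if s == 0 or not math.isfinite(s):
            raise ValueError(f"column {col!r} is constant; cannot standardize")
    z = (work - means) / stds
    return z, Standardizer(list(work.columns), means, stds, imputed)


# ---------------------------------------------------------------------------
# Ward clustering
# ---------------------------------------------------------------------------

def _lance_williams_ward(d: np.ndarray) -> np.ndarray:
    """Agglomerative Ward via the Lance-Williams recurrence on a dissimilarity matrix.

    Runs the ``ward.D`` update on the supplied dissimilarities as-is:
    ``d(k, i∪j) = ((n_i+n_k) d(k,i) + (n_j+n_k) d(k,j) - n_k d(i,j)) / (n_i+n_j+n_k)``.
    Returns a linkage array in the scipy format (cluster indices, merge
    height, merged size).
    """
    d = np.array(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("dissimilarity matrix must be square")
    np.fill_diagonal(d, np.inf)
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    ids = {i: i for i in range(n)}  # row index -> cluster id in linkage numbering
    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        sub = d[np.ix_(active, active)]
        k = np.argmin(sub)
        ai, aj = divmod(k, len(active))
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        h = d[i, j]
        ni, nj = sizes[i], sizes[j]
        lo, hi = sorted((ids[i], ids[j]))
        Z[step] = [lo, hi, h, ni + nj]
        for k2 in active:
            if k2 in (i, j):
                continue
            nk = sizes[k2]
            d[i, k2] = d[k2, i] = (
                (ni + nk) * d[i, k2] + (nj + nk) * d[j, k2] - nk * h
            ) / (ni + nj + nk)
        sizes[i] = ni + nj
        ids[i] = next_id
        next_id += 1
        active.remove(j)
    return Z


def ward_cluster(z: pd.DataFrame | np.ndarray, variant: str = "ward.D2") -> np.ndarray:
    """Ward linkage on Euclidean distances of a (standardized) feature matrix.

    ``variant="ward.D2"`` (default) is the proper Ward criterion on Euclidean
    distances; ``variant="ward.D"`` runs the Lance-Williams recurrence on
    unsquared distances, matching the legacy form.  Returns a scipy linkage
    array with monotone non-decreasing merge heights.
    """
    X = np.asarray(z, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2D matrix with at least 2 rows")
    if variant == "ward.D2":
        return hierarchy.linkage(X, method="ward")
    if variant == "ward.D":
        from scipy.spatial.distance import pdist, squareform

        return _lance_williams_ward(squareform(pdist(X)))
    raise ValueError(f"unknown Ward variant {variant!r}")


@dataclass
class ClusterAssignment:
    """Selected cut of a dendrogram with the silhouette-vs-k scan."""

    k: int
    labels: np.ndarray  # 1..k per neuron
    silhouettes: dict[int, float]  # mean silhouette width per scanned k

    @property
    def mean_silhouette(self) -> float:
        return self.silhouettes[self.k]


def silhouette_select_k(
    z: pd.DataFrame | np.ndarray,
    linkage_matrix: np.ndarray,
    k_range: range | None = None,
) -> ClusterAssignment:
    """Choose the number of clusters by the average-silhouette criterion.

    Mean silhouette width on Euclidean distances is evaluated for every cut in
    ``k_range`` (default 2..min(8, n-1)); the maximizing k wins, ties broken
    toward smaller k.  Singleton clusters contribute silhouette 0.
    """
    X = np.asarray(z, dtype=float)
    n = X.shape[0]
    if k_range is None:
        k_range = range(2, min(DEFAULT_K_MAX, n - 1) + 1)
    if len(k_range) == 0:
        raise ValueError("empty k range")
    sils: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    for k in k_range:
        if not (2 <= k <= n - 1):
            raise ValueError(f"k={k} out of range for n={n}")
        labels = hierarchy.fcluster(linkage_matrix, t=k, criterion="maxclust")
        labelings[k] = labels
        if len(np.unique(labels)) < 2:
            continue  # degenerate cut (tied heights); silhouette undefined
        sils[k] = float(silhouette_score(X, labels, metric="euclidean"))
    if not sils:
        k = min(k_range)
        warnings.warn(
            "silhouette undefined for every scanned k; returning the smallest k"
        )
        return ClusterAssignment(k=k, labels=labelings[k], silhouettes={k: math.nan})
    best_k = max(sorted(sils), key=lambda k: (sils[k], -k))
    return ClusterAssignment(k=best_k, labels=labelings[best_k], silhouettes=sils)


def dendrogram_to_newick(
    linkage_matrix: np.ndarray, leaf_names: list[str]
) -> str:
    """Export a linkage as Newick with merge-height differences as branch lengths."""
    tree = hierarchy.to_tree(linkage_matrix)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - (0.0 if node.is_leaf() else node.dist), 0.0)
        if node.is_leaf():
            length = parent_height
            return f"{leaf_names[node.id]}:{length:.10g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    body = rec(tree, tree.dist)
    return body + ";"


def linkage_to_merge_table(linkage_matrix: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        linkage_matrix,
        columns=["child_1", "child_2", "height", "size"],
    ).astype({"child_1": int, "child_2": int, "size": int})


# ---------------------------------------------------------------------------
# Statistical comparisons
# ---------------------------------------------------------------------------

def correlation_terminals(x, y) -> tuple[float, float]:
    """Pearson correlation of two equal-length terminal-count series.

    Returns ``(r, p)`` with the two-sided p-value from the t transform on
    n-2 degrees of freedom.  Zero variance in either input raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1D series with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: an input has zero variance")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class TrendResult:
    F: float
    p: float
    slope: float
    n: int


def trend_test(
    lengths,
    positions,
    populations=None,
    exclude: set[str] | frozenset[str] = frozenset(),
) -> TrendResult:
    """Single-predictor regression trend of innervation length on soma position.

    Regresses total fin afferent length on signed anteroposterior soma
    position and reports the regression ANOVA F with its two-sided p, plus the
    slope sign (a negative slope means anterior somas innervate more, given
    the anterior-negative sign convention).  ``populations``/``exclude``
    support re-running without the Rohon-Beard cells.
    """
    lengths = np.asarray(lengths, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if populations is not None and exclude:
        mask = ~np.isin(np.asarray(populations, dtype=object), list(exclude))
        lengths, positions = lengths[mask], positions[mask]
    n = len(lengths)
    if n < 3:
        raise ValueError("trend test needs at least 3 neurons after exclusion")
    if np.ptp(positions) == 0:
        raise ValueError("constant predictor: all soma positions identical")
    res = stats.linregress(positions, lengths)
    if np.ptp(lengths) == 0:
        return TrendResult(F=0.0, p=1.0, slope=0.0, n=n)
    r2 = res.rvalue**2
    F = r2 * (n - 2) / (1 - r2) if r2 < 1 else math.inf
    return TrendResult(F=float(F), p=float(res.pvalue), slope=float(res.slope), n=n)


def length_comparison(total_axial, total_fin) -> dict[str, float]:
    """Compare summed axial vs. summed fin afferent length.

    Runs the chi-square goodness-of-fit of the two summed totals against an
    equal 50/50 expectation (as printed in the original analysis; a
    statistically unusual treatment of continuous totals) and a paired
    Wilcoxon signed-rank test as a flagged nonparametric alternative.
    """
    axial = np.asarray(total_axial, dtype=float)
    fin = np.asarray(total_fin, dtype=float)
    if axial.shape != fin.shape or axial.ndim != 1 or len(axial) == 0:
        raise ValueError("need paired equal-length totals")
    if np.any(axial < 0) or np.any(fin < 0):
        raise ValueError("totals must be non-negative")
    sa, sf = float(axial.sum()), float(fin.sum())
    if sa + sf == 0:
        raise ValueError("all totals are zero")
    chi = stats.chisquare([sa, sf])
    out = {
        "chi_square_statistic": float(chi.statistic),
        "chi_square_p": float(chi.pvalue),
        "axial_total_um": sa,
        "fin_total_um": sf,
    }
    diffs = axial - fin
    if len(axial) >= 2 and np.any(diffs != 0):
        w = stats.wilcoxon(axial, fin)
        out["wilcoxon_statistic"] = float(w.statistic)
        out["wilcoxon_p"] = float(w.pvalue)
    else:
        out["wilcoxon_statistic"] = math.nan
        out["wilcoxon_p"] = math.nan
    return out


def leave_one_feature_out(
    z: pd.DataFrame, variant: str = "ward.D2", k_range: range | None = None
) -> pd.DataFrame:
    """Cluster-count stability report under leave-one-feature-out.

    For each dropped column, reclusters and reports the selected k, its mean
    silhouette, and the adjusted Rand agreement with the all-feature labels.
    Informational (no pass/fail semantics).
    """
    from sklearn.metrics import adjusted_rand_score

    full_link = ward_cluster(z, variant)
    full = silhouette_select_k(z, full_link, k_range)
    rows = [
        {
            "left_out": "(none)",
            "k": full.k,
            "mean_silhouette": full.mean_silhouette,
            "ari_vs_full": 1.0,
        }
    ]
    for col in z.columns:
        zz = z.drop(columns=[col])
        link = ward_cluster(zz, variant)
        sel = silhouette_select_k(zz, link, k_range)
        rows.append(
            {
                "left_out": col,
                "k": sel.k,
                "mean_silhouette": sel.mean_silhouette,
                "ari_vs_full": float(adjusted_rand_score(full.labels, sel.labels)),
            }
        )
    return pd.DataFrame(rows)
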