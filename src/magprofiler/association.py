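"""Category-abundance association: per-category regression and clustering.

Two complementary views of how functional gene content tracks abundance
shifts across the temperature x H2 design:

* Per-category multiple regression.  For each functional category
  separately, a contrast variable (the trait) is regressed on the per-PG
  gene count for that category plus PG completeness as a covariate (an
  incomplete genome under-counts every category, so completeness must be
  held fixed).  Reported per category: the count coefficient b, its
  two-sided p-value (the partial F test with 1 df, identically the squared
  t), and significance at P <= 0.05.  Categories are fit one at a time to
  avoid shared-variance and over-parameterization problems.

* Flexible-beta hierarchical clustering of PGs on their abundance profiles,
  via the Lance-Williams recurrence with alpha_i = alpha_j = (1-beta)/2,
  gamma = 0 (beta defaults to -0.25, the standard recommendation).  For
  beta <= 0 merge heights are monotone.  A chosen cut is summarized by the
  cluster R^2 = between-group / total sum of squares of the clustered
  values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_io import ValidationError

__all__ = [
    "RegressionResult",
    "Dendrogram",
    "fit_category_regression",
    "associate_all",
    "beta_flexible_cluster",
    "cut_dendrogram",
    "cluster_r2",
    "euclidean_distance_matrix",
]

DEFAULT_BETA = -0.25
SIGNIFICANCE_P = 0.05


@dataclass(frozen=True)
class RegressionResult:
    trait: str
    category_id: str
    coefficient: float | None  # b, the gene-count coefficient
    p_value: float | None
    n: int
    completeness_coefficient: float | None
    significant: bool
    fittable: bool


def fit_category_regression(
    trait_values,
    counts,
    completeness,
    trait: str = "",
    category_id: str = "",
) -> RegressionResult:
    """OLS of one contrast variable on (intercept, category count, completeness).

    Requires n >= 3 and a non-constant count predictor (otherwise the result
    is flagged unfittable and no p is emitted).
    """
    y = np.asarray(trait_values, dtype=float)
    x1 = np.asarray(counts, dtype=float)
    x2 = np.asarray(completeness, dtype=float)
    n = y.size
    if n < 3 or x1.size != n or x2.size != n:
        raise ValidationError("need >= 3 PGs with matching trait/count/completeness")
    if np.ptp(x1) == 0:
        return RegressionResult(trait, category_id, None, None, n, None, False, False)
    X = sm.add_constant(np.column_stack([x1, x2]), has_constant="add")
    fit = sm.OLS(y, X).fit()
    b = float(fit.params[1])
    p = float(fit.pvalues[1])
    return RegressionResult(
        trait=trait,
        category_id=category_id,
        coefficient=b,
        p_value=p,
        n=n,
        completeness_coefficient=float(fit.params[2]),
        significant=bool(p <= SIGNIFICANCE_P),
        fittable=True,
    )


def associate_all(
    contrasts: pd.DataFrame,
    profiles: pd.DataFrame,
    completeness: pd.Series,
) -> pd.DataFrame:
    """Fit every (trait, category) regression over the common PGs.

    `contrasts`: PG x contrast-variable table; `profiles`: PG x category
    gene-count table; `completeness`: per-PG percent.  Returns a tidy table
    with one row per (trait, category).
    """
    pgs = contrasts.index.intersection(profiles.index).intersection(completeness.index)
    if len(pgs) < 3:
        raise ValidationError("fewer than 3 PGs shared by all three inputs")
    rows = []
    comp = completeness.loc[pgs].to_numpy(dtype=float)
    for trait in contrasts.columns:
        y = contrasts.loc[pgs, trait].to_numpy(dtype=float)
        for cat in profiles.columns:
            res = fit_category_regression(
                y, profiles.loc[pgs, cat].to_numpy(dtype=float), comp, str(trait), str(cat)
            )
            rows.append(
                {
                    "trait": res.trait,
                    "category_id": res.category_id,
                    "b": res.coefficient,
                    "p_value": res.p_value,
                    "completeness_b": res.completeness_coefficient,
                    "n": res.n,
                    "significant": res.significant,
                    "fittable": res.fittable,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Flexible-beta (Lance-Williams) clustering


@dataclass
class Dendrogram:
    """Merge history in scipy linkage form plus the flexible-beta parameters.

    `merges` is the (n-1) x 4 array [left, right, height, size] with leaves
    labeled 0..n-1 and internal nodes n, n+1, ... in merge order, directly
    usable with scipy.cluster.hierarchy.
    """

    merges: np.ndarray
    beta: float
    n_leaves: int

    @property
    def alpha(self) -> float:
        return (1.0 - self.beta) / 2.0


def euclidean_distance_matrix(values) -> np.ndarray:
    """Pairwise Euclidean distances between PG profile rows."""
    x = np.asarray(values, dtype=float)
    diff = x[:, None, :] - x[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def beta_flexible_cluster(distance, beta: float = DEFAULT_BETA) -> Dendrogram:
    """Agglomerate by minimum distance with the Lance-Williams update.

    After merging clusters i and j, the distance from any cluster k to the
    merged node is alpha*d(k,i) + alpha*d(k,j) + beta*d(i,j) with
    alpha = (1-beta)/2.  Ties in the minimum are broken by the lowest
    (label_i, label_j) pair.
    """
    D = np.asarray(distance, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("distance must be a square matrix")
    if not np.allclose(D, D.T):
        raise ValidationError("distance matrix must be symmetric")
    if (np.diag(D) != 0).any() or (D < 0).any():
        raise ValidationError("distance matrix must be non-negative with zero diagonal")
    n = D.shape[0]
    if n < 2:
        raise ValidationError("need at least two leaves")
    alpha = (1.0 - beta) / 2.0
    cur = D.astype(float).copy()
    labels = list(range(n))  # cluster label at each active matrix position
    sizes = {i: 1 for i in range(n)}
    merges = np.empty((n - 1, 4), dtype=float)
    next_label = n
    for step in range(n - 1):
        m = cur.shape[0]
        # minimum off-diagonal distance; ties -> lowest (label_i, label_j)
        best = None
        for i in range(m - 1):
            for j in range(i + 1, m):
                key = (cur[i, j], min(labels[i], labels[j]), max(labels[i], labels[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (_, li, lj), i, j = best[0], best[1], best[2]
        height = cur[i, j]
        la, lb = labels[i], labels[j]
        merges[step] = (min(la, lb), max(la, lb), height, sizes[la] + sizes[lb])
        # Lance-Williams update against every other active cluster
        keep = [k for k in range(m) if k not in (i, j)]
        new_row = alpha * cur[keep, i] + alpha * cur[keep, j] + beta * height
        sub = cur[np.ix_(keep, keep)]
        m2 = len(keep) + 1
        nxt = np.zeros((m2, m2), dtype=float)
        nxt[:-1, :-1] = sub
        nxt[-1, :-1] = new_row
        nxt[:-1, -1] = new_row
        cur = nxt
        labels = [labels[k] for k in keep] + [next_label]
        sizes[next_label] = sizes[la] + sizes[lb]
        next_label += 1
    return Dendrogram(merges=merges, beta=beta, n_leaves=n)


def cut_dendrogram(dendrogram: Dendrogram, n_clusters: int) -> np.ndarray:
    """Flat cluster labels (0-based) for a cut into n_clusters groups."""
    from scipy.cluster.hierarchy import fcluster

    labels = fcluster(dendrogram.merges, t=n_clusters, criterion="maxclust")
    return labels - labels.min()


def cluster_r2(labels, values) -> float:
    """Between-group over total sum of squares of the clustered values.

    `values` may be a vector or a PG x variable matrix (sums of squares are
    pooled over variables).  Singleton-only partitions give 1, a single
    cluster gives 0, and a zero total SS is reported as 0 with a warning.
    """
    import warnings

    y = np.asarray(values, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    lab = np.asarray(labels)
    if lab.size != y.shape[0]:
        raise ValidationError("labels and values must have matching length")
    grand = y.mean(axis=0)
    sst = float(((y - grand) ** 2).sum())
    if sst == 0:
        warnings.warn("zero total sum of squares: R^2 reported as 0", stacklevel=2)
        return 0.0
    ssb = 0.0
    for g in np.unique(lab):
        mask = lab == g
        ssb += mask.sum() * float(((y[mask].mean(axis=0) - grand) ** 2).sum())
    return ssb / sst
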