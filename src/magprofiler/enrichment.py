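"""Randomization test for per-PG functional-category enrichment.

For every PG and functional category (KEGG map, COG, SEED subsystem), the
observed statistic is N, the number of the PG's genes carrying the category.
The null model draws the same number of genes uniformly at random, without
replacement, from the entire assembly's gene pool and recounts the category.
The empirical p-value is the fraction of random draws in which the category
count is equal to or higher than N; the default 1000 repetitions give a p
resolution of 0.001, and significance is declared at alpha = 0.05.

Because a PG's genes are a subset of the assembly, the analytic form of this
null is the hypergeometric upper tail, provided as an exact oracle that the
sampled p converges to (and as a fast with-replacement binomial variant).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CategoryCatalog, GeneRecord, ValidationError

__all__ = [
    "CategoryProfile",
    "EnrichmentResult",
    "count_categories",
    "permutation_enrichment",
    "hypergeometric_tail",
    "enrich_all",
]

DEFAULT_REPS = 1000
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class CategoryProfile:
    """Distinct-gene counts per functional category for one PG."""

    pg_id: str
    counts: dict[str, int]
    pg_gene_total: int


@dataclass(frozen=True)
class EnrichmentResult:
    pg_id: str
    category_id: str
    observed: int
    empirical_p: float
    exact_p: float
    reps: int
    alpha: float
    significant: bool
    seed: int


def count_categories(
    genes: Sequence[GeneRecord], catalog: CategoryCatalog | None = None, pg_id: str | None = None
) -> CategoryProfile:
    """Count, per category, the distinct genes of one PG carrying it.

    A gene with several categories contributes once to each; a gene
    annotated twice to the same category counts once (set semantics).
    Categories absent from the catalog are counted under their literal id
    with a warning.
    """
    import warnings

    if pg_id is None:
        pg_id = genes[0].pg_id if genes else ""
    counts: dict[str, int] = {}
    unknown: set[str] = set()
    for g in genes:
        for c in g.categories:
            counts[c] = counts.get(c, 0) + 1
            if catalog is not None and c not in catalog.entries:
                unknown.add(c)
    if unknown:
        warnings.warn(
            f"PG {pg_id}: {len(unknown)} category ids not in catalog "
            f"(counted under their literal ids)",
            stacklevel=2,
        )
    return CategoryProfile(pg_id=pg_id, counts=counts, pg_gene_total=len(genes))


def hypergeometric_tail(
    pool_size: int, category_total: int, draw_size: int, n_observed: int
) -> float:
    """P(X >= N) for X ~ Hypergeometric(pool_size, category_total, draw_size).

    The analytic null of the permutation test: probability that a uniform
    random subset of `draw_size` genes from a pool containing
    `category_total` category members includes at least `n_observed` of them.
    """
    if n_observed < 0 or not (0 <= draw_size <= pool_size):
        raise ValidationError(
            f"need N >= 0 and 0 <= draw_size ({draw_size}) <= pool ({pool_size})"
        )
    if not (0 <= category_total <= pool_size):
        raise ValidationError("category_total must be within [0, pool_size]")
    if n_observed == 0:
        return 1.0
    if n_observed > min(draw_size, category_total):
        return 0.0  # impossible count
    return float(stats.hypergeom.sf(n_observed - 1, pool_size, category_total, draw_size))


def _null_counts(
    membership: np.ndarray, draw_size: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Category counts of `reps` uniform random subsets of size draw_size.

    Vectorized subset sampling: the indices of the `draw_size` smallest of n
    iid uniforms form a uniform random subset.  Processed in chunks to bound
    memory.
    """
    n = membership.size
    out = np.empty(reps, dtype=np.int64)
    chunk = max(1, int(2_000_000 // max(n, 1)))
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        keys = rng.random((m, n))
        idx = np.argpartition(keys, draw_size - 1, axis=1)[:, :draw_size]
        out[done : done + m] = membership[idx].sum(axis=1)
        done += m
    return out


def permutation_enrichment(
    pg_gene_total: int,
    observed: int,
    pool_categories: Sequence[Iterable[str]] | np.ndarray,
    category_id: str,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    pg_id: str = "",
    with_replacement: bool = False,
    add_one: bool = False,
) -> EnrichmentResult:
    """Seeded random-sampling enrichment test for one (PG, category) pair.

    `pool_categories` is the assembly-wide gene table: one entry per gene,
    either an iterable of its category ids or, equivalently, a boolean
    membership array for `category_id`.  Each repetition draws
    `pg_gene_total` genes from the pool without replacement (binomial
    with-replacement variant behind the flag) and the empirical p is the
    plain fraction of draws reaching the observed count (add-one correction
    behind a flag).
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    if isinstance(pool_categories, np.ndarray) and pool_categories.dtype == bool:
        membership = pool_categories
    else:
        membership = np.array(
            [category_id in cats for cats in pool_categories], dtype=bool
        )
    pool_size = membership.size
    if pg_gene_total > pool_size:
        raise ValidationError(
            f"PG gene total ({pg_gene_total}) exceeds pool size ({pool_size})"
        )
    rng = np.random.default_rng(seed)
    if with_replacement:
        draws = rng.choice(pool_size, size=(reps, pg_gene_total), replace=True)
        counts = membership[draws].sum(axis=1)
    else:
        counts = _null_counts(membership, pg_gene_total, reps, rng)
    hits = int((counts >= observed).sum())
    empirical_p = (hits + 1) / (reps + 1) if add_one else hits / reps
    k = int(membership.sum())
    if with_replacement:
        exact_p = (
            1.0
            if observed == 0
            else float(stats.binom.sf(observed - 1, pg_gene_total, k / pool_size))
        )
    else:
        exact_p = hypergeometric_tail(pool_size, k, pg_gene_total, observed)
    return EnrichmentResult(
        pg_id=pg_id,
        category_id=category_id,
        observed=observed,
        empirical_p=float(empirical_p),
        exact_p=exact_p,
        reps=reps,
        alpha=alpha,
        significant=empirical_p < alpha,
        seed=seed,
    )


def enrich_all(
    annotations: pd.DataFrame,
    reps: int = DEFAULT_REPS,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    categories: Sequence[str] | None = None,
    pg_gene_totals: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Run the enrichment test for every (PG, category) pair of a table.

    `annotations` has columns gene_id, pg_id, category_id (one row per
    gene-category assignment; genes without categories may appear with a
    null category_id so PG gene totals are right, or totals can be passed
    via `pg_gene_totals`).  Each (PG, category) test gets its own seed
    derived reproducibly from `seed`.
    """
    for col in ("gene_id", "pg_id", "category_id"):
        if col not in annotations.columns:
            raise ValidationError(f"annotations table lacks column {col!r}")
    genes = annotations[["gene_id", "pg_id"]].drop_duplicates()
    gene_ids = genes["gene_id"].to_numpy()
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    pool_size = len(gene_ids)
    cats = annotations.dropna(subset=["category_id"])
    all_categories = (
        list(categories) if categories is not None else sorted(cats["category_id"].unique())
    )
    membership: dict[str, np.ndarray] = {}
    for c in all_categories:
        mask = np.zeros(pool_size, dtype=bool)
        for g in cats.loc[cats["category_id"] == c, "gene_id"].unique():
            mask[gene_pos[g]] = True
        membership[c] = mask
    totals = (
        dict(pg_gene_totals)
        if pg_gene_totals is not None
        else genes.groupby("pg_id").size().to_dict()
    )
    observed = (
        cats.drop_duplicates(["gene_id", "pg_id", "category_id"])
        .groupby(["pg_id", "category_id"])
        .size()
    )
    ss = np.random.SeedSequence(seed)
    rows = []
    pg_list = sorted(totals)
    child_seeds = ss.generate_state(len(pg_list) * len(all_categories), dtype=np.uint32)
    i = 0
    for pg in pg_list:
        for c in all_categories:
            obs = int(observed.get((pg, c), 0))
            res = permutation_enrichment(
                totals[pg],
                obs,
                membership[c],
                c,
                reps=reps,
                seed=int(child_seeds[i]),
                alpha=alpha,
                pg_id=pg,
            )
            i += 1
            rows.append(
                {
                    "pg_id": pg,
                    "category_id": c,
                    "observed": obs,
                    "empirical_p": res.empirical_p,
                    "exact_p": res.exact_p,
                    "significant": res.significant,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["pg_id", "category_id", "observed", "empirical_p", "exact_p", "significant"],
    )
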