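"""Seeded synthetic-community generator with known ground truth.

Emulates the data layout of a genome-centric study of two biogas-upgrading
reactors sampled before and after H2 injection: ~200 population genomes
observed in four conditions (C1 meso pre-H2, C2 meso post-H2, C3 thermo
pre-H2, C4 thermo post-H2), each PG carrying a few hundred protein-coding
genes annotated to functional categories.  Everything downstream of
assembly/binning is generated: the per-PG quality table, the PG x sample
coverage matrix with per-sample read totals, gene FASTA, the gene ->
category annotation table, and optionally reference gene sets at controlled
nucleotide divergence.  A truth table records every planted effect so
parameter-recovery tests can close the loop.

Model choices: coverage is baseline x 2^(planted log2 effects) x log-normal
noise (coverage is positive and heavy-tailed); gene categories are
independent Bernoulli draws from per-category background frequencies,
multiplied by the planted fold for enriched (PG, category) pairs; gene
lengths are uniform in a range and composition is uniform over ACGT (codon
structure is irrelevant to every statistic computed here).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .abundance import CONTRAST_NAMES, CoverageMatrix
from .core_io import (
    GeneRecord,
    ValidationError,
    write_annotation_table,
    write_gene_fasta,
)

__all__ = ["SimulationConfig", "Community", "generate_community", "mutate_sequence", "make_reference"]

# which conditions a planted effect on each contrast variable multiplies
_EFFECT_TARGETS = {
    "mean_thermo_meso": ("C3", "C4"),
    "mean_post_pre": ("C2", "C4"),
    "meso_post_pre": ("C2",),
    "thermo_post_pre": ("C4",),
    "pre_thermo_meso": ("C3",),
    "post_thermo_meso": ("C4",),
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _default_category_freqs(n: int) -> dict[str, float]:
    # background frequencies spanning 0.5%..10%, geometric spacing
    freqs = np.geomspace(0.005, 0.10, n)
    return {f"CAT{i:03d}": float(f) for i, f in enumerate(freqs)}


@dataclass
class SimulationConfig:
    """Study-shaped defaults; every run must carry an explicit seed.

    Defaults emulate the study scale: ~200 PGs over the 4 conditions,
    baseline coverage log-normal (median 1.5, sigma 2 on log2, so roughly a
    sixth of PGs exceed the abundance threshold of 5), multiplicative
    coverage noise of 0.25 log2 units, completeness U(40,100)% and
    contamination Exp(5)% so most but not all PGs pass the eligibility
    filter, genes of 300-1500 bp, and distinct per-sample read totals so
    depth normalization is non-trivial.
    """

    seed: int
    n_pgs: int = 200
    genes_per_pg: tuple[int, int] = (150, 250)
    gene_length: tuple[int, int] = (300, 1500)
    category_freqs: dict[str, float] | None = None
    n_categories: int = 20
    planted_enrichments: list[tuple[str, str, float]] = field(default_factory=list)
    planted_contrast_effects: list[tuple[str, str, float]] = field(default_factory=list)
    coverage_noise_sd: float = 0.25  # SD of log2 multiplicative noise
    baseline_coverage: float | None = None  # fixed baseline; None -> log-normal
    baseline_median: float = 1.5
    baseline_log2_sd: float = 2.0
    completeness_range: tuple[float, float] = (40.0, 100.0)
    contamination_scale: float = 5.0
    reference_divergence: float = 0.05
    read_totals_range: tuple[int, int] = (1_000_000, 2_500_000)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        if self.category_freqs is None:
            self.category_freqs = _default_category_freqs(self.n_categories)
        for _, _, fold in self.planted_enrichments:
            if fold <= 0:
                raise ValidationError("enrichment folds must be positive")
        for _, var, _ in self.planted_contrast_effects:
            if var not in _EFFECT_TARGETS:
                raise ValidationError(f"unknown contrast variable {var!r}")


@dataclass
class Community:
    """All generated inputs plus the planted-effect truth table."""

    quality: pd.DataFrame
    coverage: CoverageMatrix
    genes: list[GeneRecord]
    annotations: pd.DataFrame
    truth: pd.DataFrame
    design: dict[str, str]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def generate_community(config: SimulationConfig) -> Community:
    """Generate the full input bundle; fully reproducible from config.seed."""
    rng = np.random.default_rng(config.seed)
    pg_ids = [f"SPG{i:03d}" for i in range(config.n_pgs)]

    # quality table
    lo, hi = config.completeness_range
    completeness = rng.uniform(lo, hi, size=config.n_pgs)
    contamination = np.clip(
        rng.exponential(config.contamination_scale, size=config.n_pgs), 0.0, 40.0
    )
    quality = pd.DataFrame(
        {
            "pg_id": pg_ids,
            "completeness": np.round(completeness, 2),
            "contamination": np.round(contamination, 2),
        }
    )

    # coverage: baseline x 2^(planted) x log-normal noise
    if config.baseline_coverage is not None:
        baseline = np.full(config.n_pgs, float(config.baseline_coverage))
    else:
        baseline = config.baseline_median * 2.0 ** rng.normal(
            0.0, config.baseline_log2_sd, size=config.n_pgs
        )
    log2_mult = pd.DataFrame(
        np.zeros((config.n_pgs, 4)), index=pg_ids, columns=["C1", "C2", "C3", "C4"]
    )
    truth_rows = []
    for pg, var, effect in config.planted_contrast_effects:
        if pg not in log2_mult.index:
            raise ValidationError(f"planted effect on unknown PG {pg!r}")
        for cond in _EFFECT_TARGETS[var]:
            log2_mult.at[pg, cond] += effect
        truth_rows.append(
            {"kind": "contrast", "pg_id": pg, "target": var, "value": effect}
        )
    noise = rng.normal(0.0, config.coverage_noise_sd, size=(config.n_pgs, 4))
    values = baseline[:, None] * 2.0 ** (log2_mult.to_numpy() + noise)
    sample_ids = ["S1", "S2", "S3", "S4"]
    design = dict(zip(sample_ids, ["C1", "C2", "C3", "C4"]))
    # distinct read totals so normalization is non-trivial; `values` above
    # are the intended post-normalization coverages, so emit raw coverage
    # that depth normalization maps back onto them exactly
    totals = rng.choice(
        np.arange(config.read_totals_range[0], config.read_totals_range[1], 1000),
        size=4,
        replace=False,
    ).astype(float)
    raw = values * (totals / totals.min())[None, :]
    coverage = CoverageMatrix(
        values=pd.DataFrame(raw, index=pg_ids, columns=sample_ids),
        read_totals=pd.Series(totals, index=sample_ids),
        normalized=False,
    )

    # genes and annotations
    enriched = {(pg, cat): fold for pg, cat, fold in config.planted_enrichments}
    for (pg, cat), fold in enriched.items():
        freq = config.category_freqs.get(cat)
        if freq is None:
            raise ValidationError(f"planted enrichment on unknown category {cat!r}")
        if freq * fold > 1.0:
            raise ValidationError(
                f"infeasible enrichment: {cat} frequency {freq} x fold {fold} > 1"
            )
        truth_rows.append({"kind": "enrichment", "pg_id": pg, "target": cat, "value": fold})
    cat_ids = list(config.category_freqs)
    base_freqs = np.array([config.category_freqs[c] for c in cat_ids])
    genes: list[GeneRecord] = []
    ann_rows: list[dict] = []
    g_lo, g_hi = config.genes_per_pg
    for pg in pg_ids:
        n_genes = int(rng.integers(g_lo, g_hi + 1))
        freqs = base_freqs.copy()
        for ci, cat in enumerate(cat_ids):
            fold = enriched.get((pg, cat))
            if fold is not None:
                freqs[ci] = base_freqs[ci] * fold
        carries = rng.random((n_genes, len(cat_ids))) < freqs[None, :]
        lengths = rng.integers(config.gene_length[0], config.gene_length[1] + 1, size=n_genes)
        for gi in range(n_genes):
            gene_id = f"{pg}_g{gi:04d}"
            cats = {cat_ids[ci] for ci in np.nonzero(carries[gi])[0]}
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    pg_id=pg,
                    sequence=_random_sequence(rng, int(lengths[gi])),
                    categories=cats,
                )
            )
            ann_rows.append({"gene_id": gene_id, "pg_id": pg, "category_id": None})
            for cat in sorted(cats):
                ann_rows.append({"gene_id": gene_id, "pg_id": pg, "category_id": cat})
    annotations = pd.DataFrame(ann_rows, columns=["gene_id", "pg_id", "category_id"])
    # keep the null-category placeholder row only for genes with no category
    with_cat = set(annotations.dropna(subset=["category_id"])["gene_id"])
    annotations = annotations[
        annotations["category_id"].notna() | ~annotations["gene_id"].isin(with_cat)
    ].reset_index(drop=True)

    truth = pd.DataFrame(truth_rows, columns=["kind", "pg_id", "target", "value"])
    return Community(
        quality=quality,
        coverage=coverage,
        genes=genes,
        annotations=annotations,
        truth=truth,
        design=design,
    )


def mutate_sequence(sequence: str, rate: float, seed: int | np.random.Generator) -> str:
    """Substitute each A/C/G/T site independently at the given rate, always
    to a different base; non-ACGT sites are left unchanged.

    Expected identity of the result to the input is 1 - rate.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValidationError("rate must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    valid = np.isin(arr, _BASES)
    hit = valid & (rng.random(arr.size) < rate)
    if hit.any():
        # shift each hit base by 1-3 positions in the ACGT alphabet
        base_idx = np.searchsorted(np.sort(_BASES), arr[hit])
        order = np.argsort(_BASES)  # ACGT already sorted, identity
        shifts = rng.integers(1, 4, size=int(hit.sum()))
        arr[hit] = _BASES[(base_idx + shifts) % 4]
    return arr.tobytes().decode()


def make_reference(
    genes: list[GeneRecord], rate: float, seed: int, ref_id: str | None = None
) -> list[GeneRecord]:
    """Reference gene set derived from a PG's genes at per-site divergence
    `rate` (supports ANI validation at known ground truth)."""
    rng = np.random.default_rng(seed)
    ref_id = ref_id or f"REF_{genes[0].pg_id}" if genes else "REF"
    return [
        GeneRecord(
            gene_id=f"{ref_id}_{g.gene_id}",
            pg_id=ref_id,
            sequence=mutate_sequence(g.sequence or "", rate, rng),
            categories=set(g.categories),
        )
        for g in genes
    ]


def write_community(community: Community, outdir) -> dict[str, Path]:
    """Write the community in exactly the formats the pipeline reads."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "quality": out / "quality.tsv",
        "coverage": out / "coverage.tsv",
        "read_totals": out / "read_totals.tsv",
        "design": out / "design.tsv",
        "genes": out / "genes.fasta",
        "annotations": out / "annotations.tsv",
        "truth": out / "truth.tsv",
    }
    community.quality.to_csv(paths["quality"], sep="\t", index=False)
    community.coverage.values.rename_axis("pg_id").reset_index().to_csv(
        paths["coverage"], sep="\t", index=False
    )
    community.coverage.read_totals.rename_axis("sample_id").rename("read_total").reset_index().to_csv(
        paths["read_totals"], sep="\t", index=False
    )
    pd.DataFrame(
        {"sample_id": list(community.design), "condition": list(community.design.values())}
    ).to_csv(paths["design"], sep="\t", index=False)
    write_gene_fasta(community.genes, paths["genes"])
    write_annotation_table(community.genes, paths["annotations"])
    community.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
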