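"""Domain types and readers/writers shared by every pipeline stage.

A *population genome* (PG, synonym MAG) is a microbial genome reconstructed
from a metagenomic assembly by binning, without isolation of the organism.
This module holds the per-PG quality record (CheckM-style completeness and
contamination percentages), the MIMAG draft-quality tiers derived from them,
the eligibility filter used to select PGs for metabolic reconstruction, and
plain-text readers/writers for the quality table, gene FASTA and gene →
functional-category annotation table.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "ValidationError",
    "Tier",
    "QualityRecord",
    "GeneRecord",
    "CategoryCatalog",
    "mimag_tier",
    "is_eligible",
    "read_quality_table",
    "write_quality_table",
    "read_gene_fasta",
    "write_gene_fasta",
    "read_annotation_table",
    "read_catalog",
    "write_table",
    "read_table",
]


class FormatError(ValueError):
    """Malformed input file (missing column, bad header, duplicate id)."""


class ValidationError(ValueError):
    """Well-formed input carrying an out-of-range or inconsistent value."""


class Tier(str, enum.Enum):
    """MIMAG draft-quality tier of a metagenome-assembled genome."""

    HIGH = "high"
    MEDIUM = "medium"
    LOW = "low"


def _check_percent(name: str, value: float, context: str = "") -> None:
    if not (0.0 <= value <= 100.0):
        where = f" ({context})" if context else ""
        raise ValidationError(f"{name} must be in [0, 100], got {value!r}{where}")


def mimag_tier(completeness: float, contamination: float) -> Tier:
    """MIMAG draft tier from completeness/contamination percentages.

    high-quality draft: completeness > 90 and contamination < 5;
    medium-quality draft: completeness >= 50 and contamination < 10;
    anything else is a low-quality draft.  Boundaries follow the MIMAG
    standard (Bowers et al. 2017): the high tier is strict in completeness,
    the medium tier inclusive.
    """
    _check_percent("completeness", completeness)
    _check_percent("contamination", contamination)
    if completeness > 90.0 and contamination < 5.0:
        return Tier.HIGH
    if completeness >= 50.0 and contamination < 10.0:
        return Tier.MEDIUM
    return Tier.LOW


def is_eligible(
    completeness: float,
    contamination: float,
    completeness_alt: float | None = None,
    contamination_alt: float | None = None,
) -> bool:
    """Reconstruction-eligibility filter: completeness > 50 and contamination < 20.

    Both inequalities are strict.  Quality estimates are sometimes computed
    twice (e.g. two CheckM runs on different scaffold sets); if a second pair
    is given, the PG is eligible when EITHER pair passes.
    """
    _check_percent("completeness", completeness)
    _check_percent("contamination", contamination)
    ok = completeness > 50.0 and contamination < 20.0
    if completeness_alt is not None and contamination_alt is not None:
        _check_percent("completeness_alt", completeness_alt)
        _check_percent("contamination_alt", contamination_alt)
        ok = ok or (completeness_alt > 50.0 and contamination_alt < 20.0)
    return ok


@dataclass(frozen=True)
class QualityRecord:
    """Per-PG quality: completeness/contamination with derived tier and flag."""

    pg_id: str
    completeness: float
    contamination: float
    genome_size: int | None = None
    tier: Tier = Tier.LOW
    eligible: bool = False

    @classmethod
    def from_values(
        cls,
        pg_id: str,
        completeness: float,
        contamination: float,
        genome_size: int | None = None,
        completeness_alt: float | None = None,
        contamination_alt: float | None = None,
    ) -> "QualityRecord":
        return cls(
            pg_id=pg_id,
            completeness=float(completeness),
            contamination=float(contamination),
            genome_size=genome_size,
            tier=mimag_tier(completeness, contamination),
            eligible=is_eligible(
                completeness, contamination, completeness_alt, contamination_alt
            ),
        )


@dataclass
class GeneRecord:
    """One protein-coding gene: id, owning PG, nucleotide sequence, categories.

    A gene may belong to several functional categories (KEGG map, COG, SEED);
    `categories` is a set so each (gene, category) pair counts at most once.
    """

    gene_id: str
    pg_id: str
    sequence: str | None = None
    categories: set[str] = field(default_factory=set)


@dataclass
class CategoryCatalog:
    """Mapping category_id -> (namespace, display name).

    Category ids are namespace-prefixed (e.g. ``KEGG:ko00720``) so they stay
    unique across the KEGG/COG/SEED namespaces.
    """

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)

    def namespace(self, category_id: str) -> str | None:
        ent = self.entries.get(category_id)
        return ent[0] if ent else None


# ---------------------------------------------------------------------------
# Tabular IO


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def read_quality_table(path) -> list[QualityRecord]:
    """Read a tab-separated quality table into QualityRecords.

    Required header columns: pg_id, completeness, contamination.  Optional:
    genome_size, completeness_alt, contamination_alt (second quality
    estimate; eligibility uses OR logic over the two pairs).
    """
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["pg_id", "completeness", "contamination"], path)
    has_alt = "completeness_alt" in df.columns and "contamination_alt" in df.columns
    records = []
    for i, row in df.iterrows():
        try:
            alt_c = alt_k = None
            if has_alt and pd.notna(row["completeness_alt"]):
                alt_c = float(row["completeness_alt"])
                alt_k = float(row["contamination_alt"])
            records.append(
                QualityRecord.from_values(
                    str(row["pg_id"]),
                    float(row["completeness"]),
                    float(row["contamination"]),
                    genome_size=(
                        int(row["genome_size"])
                        if "genome_size" in df.columns and pd.notna(row["genome_size"])
                        else None
                    ),
                    completeness_alt=alt_c,
                    contamination_alt=alt_k,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i} ({row['pg_id']}): {exc}") from exc
    return records


def write_quality_table(records: Iterable[QualityRecord], path) -> None:
    df = pd.DataFrame(
        {
            "pg_id": [r.pg_id for r in records],
            "completeness": [r.completeness for r in records],
            "contamination": [r.contamination for r in records],
            "genome_size": [r.genome_size for r in records],
            "tier": [r.tier.value for r in records],
            "eligible": [r.eligible for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path) -> None:
    """Write any result table as UTF-8 TSV with header."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Sequence IO

_VALID_BASES = set("ACGTN")


def read_gene_fasta(path, delimiter: str = "|") -> list[GeneRecord]:
    """Read gene nucleotide sequences whose headers carry gene and PG ids.

    Header format is ``gene_id<delimiter>pg_id``.  Sequences are uppercased;
    characters outside {A,C,G,T,N} raise.  Duplicate gene ids are an error;
    an empty file yields an empty list.
    """
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if delimiter not in rec.id:
            raise FormatError(
                f"{path}: header {rec.id!r} lacks delimiter {delimiter!r} "
                "(expected gene_id<delim>pg_id)"
            )
        gene_id, pg_id = rec.id.split(delimiter, 1)
        if gene_id in seen:
            raise FormatError(f"{path}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValidationError(
                f"{path}: gene {gene_id!r} has invalid bases {sorted(bad)!r}"
            )
        genes.append(GeneRecord(gene_id=gene_id, pg_id=pg_id, sequence=seq))
    return genes


def write_gene_fasta(genes: Iterable[GeneRecord], path, delimiter: str = "|") -> None:
    records = [
        SeqRecord(Seq(g.sequence or ""), id=f"{g.gene_id}{delimiter}{g.pg_id}", description="")
        for g in genes
    ]
    SeqIO.write(records, str(path), "fasta")


def read_annotation_table(path, genes: Sequence[GeneRecord]) -> int:
    """Apply (gene_id, category_id) annotation rows to GeneRecords in place.

    Returns the number of rows skipped because their gene_id is unknown
    (also reported as a warning so pipelines surface silent mismatches).
    """
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["gene_id", "category_id"], path)
    by_id = {g.gene_id: g for g in genes}
    skipped = 0
    for gene_id, category_id in zip(df["gene_id"], df["category_id"]):
        gene = by_id.get(str(gene_id))
        if gene is None:
            skipped += 1
            continue
        gene.categories.add(str(category_id))
    if skipped:
        warnings.warn(
            f"{path}: skipped {skipped} annotation rows with unknown gene_id",
            stacklevel=2,
        )
    return skipped


def write_annotation_table(genes: Iterable[GeneRecord], path) -> None:
    rows = [
        {"gene_id": g.gene_id, "pg_id": g.pg_id, "category_id": c}
        for g in genes
        for c in sorted(g.categories)
    ]
    pd.DataFrame(rows, columns=["gene_id", "pg_id", "category_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_catalog(path) -> CategoryCatalog:
    """Read a category catalog TSV: category_id, namespace, name."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["category_id", "namespace", "name"], path)
    entries: dict[str, tuple[str, str]] = {}
    for _, row in df.iterrows():
        cid = str(row["category_id"])
        if cid in entries:
            raise FormatError(f"{path}: duplicate category_id {cid!r}")
        entries[cid] = (str(row["namespace"]), str(row["name"]))
    return CategoryCatalog(entries=entries)


def replay_quality_summary(
    path, abundance_threshold: float = 5.0, eligible_only: bool = True
) -> dict[str, int]:
    """Summarise a per-PG quality + coverage table.

    Expects the quality columns of `read_quality_table` plus optional
    per-condition coverage columns named ``coverage_*``.  Returns the counts
    of medium- and high-quality drafts (by default among eligible PGs only,
    i.e. those selected for metabolic reconstruction; set
    ``eligible_only=False`` to tier the full table) and, when coverage
    columns are present, the number of abundant PGs (coverage above the
    threshold in at least one condition).
    """
    records = read_quality_table(path)
    pool = [r for r in records if r.eligible] if eligible_only else records
    out = {
        "n_pgs": len(records),
        "n_eligible": sum(r.eligible for r in records),
        "n_medium": sum(r.tier is Tier.MEDIUM for r in pool),
        "n_high": sum(r.tier is Tier.HIGH for r in pool),
    }
    df = pd.read_csv(path, sep="\t")
    cov_cols = [c for c in df.columns if c.startswith("coverage")]
    if cov_cols:
        out["n_abundant"] = int((df[cov_cols] > abundance_threshold).any(axis=1).sum())
    return out
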