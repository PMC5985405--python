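"""Metabolic role assignment for syntrophs in H2-fed anaerobic digesters.

The Wood-Ljungdahl (WL, reductive acetyl-CoA) pathway is reversible: run
oxidatively it underlies syntrophic acetate oxidation (SAO), run reductively
it is homoacetogenesis (H2 + CO2 -> acetate).  Gene content alone cannot
tell the direction, but the response to an H2 pulse can: raising the H2
partial pressure makes acetate oxidation endergonic (SAOB collapse in
abundance) while favoring hydrogen-consuming acetogens.  A PG with a nearly
complete WL pathway (>= 8 pathway genes by KEGG annotation) is therefore
classified by its post/pre-H2 abundance contrast:

    <= 2-fold decrease            -> SAOB candidate
    >= 2-fold increase            -> homoacetogen candidate
    stable (< 1.5-fold change)    -> WL bidirectional / metabolically flexible
    in between                    -> indeterminate

Volatile-fatty-acid degraders are labeled from enrichment of the Propanoate
and Butanoate metabolism categories: enriched in one, the other, or both.
Degrader labels may co-occur with WL labels (SAO combined with butyrate
oxidation is documented in syntrophic consortia).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .core_io import ValidationError

__all__ = [
    "RoleThresholds",
    "RoleCall",
    "wl_completeness",
    "classify_wl_direction",
    "classify_degrader",
    "role_report",
    "read_pathway_table",
    "load_wl_gene_config",
    "bundled_pathway_table",
]

WL_NEARLY_COMPLETE = 8  # inclusive gene-count threshold

# role labels
SAOB = "SAOB_candidate"
HOMOACETOGEN = "homoacetogen_candidate"
WL_BIDIRECTIONAL = "WL_bidirectional"
INDETERMINATE = "indeterminate"
PROPIONATE = "propionate_degrader"
BUTYRATE = "butyrate_degrader"
PROP_BUT = "prop_but_degrader"
NONE = "none"


@dataclass(frozen=True)
class RoleThresholds:
    """Direction thresholds on the post/pre-H2 log2 contrast.

    `t_inhibit`/`t_favor` are log2 units (default 1, i.e. a 2-fold change);
    `stable_fold` bounds the linear fold change of PGs called stable
    (default 1.5-fold, i.e. |contrast| < log2 1.5 ~ 0.585).
    """

    t_inhibit: float = 1.0
    t_favor: float = 1.0
    stable_fold: float = 1.5

    @property
    def stable_log2(self) -> float:
        return math.log2(self.stable_fold)


@dataclass
class RoleCall:
    """Role labels for one PG with the evidence that triggered each."""

    pg_id: str
    wl_count: int = 0
    wl_nearly_complete: bool = False
    prop_count: int = 0
    but_count: int = 0
    tca_count: int = 0
    cfp_count: int = 0
    fad_count: int = 0
    fdhf_isoforms: int = 0
    h2_response: float | None = None
    roles: set[str] = field(default_factory=set)
    evidence: list[str] = field(default_factory=list)


def wl_completeness(wl_count: int, threshold: int = WL_NEARLY_COMPLETE) -> tuple[int, bool]:
    """Gene count on the WL pathway and the nearly-complete flag (>= 8)."""
    if wl_count < 0:
        raise ValidationError("wl_count must be >= 0")
    return wl_count, wl_count >= threshold


def classify_wl_direction(
    wl_nearly_complete: bool,
    h2_response: float | None,
    thresholds: RoleThresholds = RoleThresholds(),
) -> str:
    """Direction label for a WL-carrying PG from its post/pre-H2 contrast."""
    if not wl_nearly_complete:
        return NONE
    if h2_response is None or not math.isfinite(h2_response):
        raise ValidationError("WL direction needs a finite post/pre-H2 contrast")
    if h2_response <= -thresholds.t_inhibit:
        return SAOB
    if h2_response >= thresholds.t_favor:
        return HOMOACETOGEN
    if abs(h2_response) < thresholds.stable_log2:
        return WL_BIDIRECTIONAL
    return INDETERMINATE


def classify_degrader(prop_enriched: bool, but_enriched: bool) -> str:
    """Propionate/butyrate degrader label from the two enrichment flags."""
    if prop_enriched and but_enriched:
        return PROP_BUT
    if prop_enriched:
        return PROPIONATE
    if but_enriched:
        return BUTYRATE
    return NONE


def _pick_h2_response(row: pd.Series, coverage_pre: pd.Series | None) -> float | None:
    """Choose the relevant post/pre contrast for a PG.

    The response to H2 is judged within the community the PG actually
    dominates: variable (iii) meso_post_pre for mesophilic-dominant PGs,
    (iv) thermo_post_pre for thermophilic-dominant ones (dominance = larger
    pre-H2 coverage).  When dominance is unknown and only one contrast is
    recorded, that one is used; with both present the larger-magnitude one
    is taken as the acting community.
    """
    meso = row.get("meso_post_pre")
    thermo = row.get("thermo_post_pre")
    meso = None if meso is None or (isinstance(meso, float) and math.isnan(meso)) else float(meso)
    thermo = (
        None if thermo is None or (isinstance(thermo, float) and math.isnan(thermo)) else float(thermo)
    )
    if coverage_pre is not None:
        c1 = float(coverage_pre.get("C1", 0.0))
        c3 = float(coverage_pre.get("C3", 0.0))
        preferred = thermo if c3 >= c1 else meso
        if preferred is not None:
            return preferred
    if meso is None:
        return thermo
    if thermo is None:
        return meso
    return thermo if abs(thermo) >= abs(meso) else meso


def role_report(
    profiles: pd.DataFrame,
    thresholds: RoleThresholds = RoleThresholds(),
    degrader_mode: str = "significance",
    prop_count_threshold: int = 14,
    but_count_threshold: int = 14,
    pre_h2_coverage: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Materialize per-PG role calls and a label summary.

    `profiles` is a per-PG table (one row per PG) with pathway gene-count
    columns (wl, prop, but, and optionally tca, cfp, fad, fdhf), the
    post/pre-H2 contrasts (meso_post_pre and/or thermo_post_pre) and, in
    significance mode, boolean enrichment flags prop_sig/but_sig from the
    enrichment module.  `degrader_mode` is "significance" (default) or
    "count" (count thresholds, e.g. for replaying published tables).
    `pre_h2_coverage`, if given, is a PG x condition table used to pick the
    dominant community's contrast.  Output is deterministic and sorted by
    pg_id; missing fields stay NaN and yield no label.
    """
    if degrader_mode not in ("significance", "count"):
        raise ValidationError("degrader_mode must be 'significance' or 'count'")
    if "pg_id" not in profiles.columns:
        raise ValidationError("profiles table lacks column 'pg_id'")
    rows = []
    for _, row in profiles.sort_values("pg_id").iterrows():
        pg = str(row["pg_id"])
        call = RoleCall(pg_id=pg)
        wl = int(row["wl"]) if "wl" in row and pd.notna(row.get("wl")) else 0
        call.wl_count, call.wl_nearly_complete = wl_completeness(wl)
        for attr, col in (
            ("prop_count", "prop"),
            ("but_count", "but"),
            ("tca_count", "tca"),
            ("cfp_count", "cfp"),
            ("fad_count", "fad"),
            ("fdhf_isoforms", "fdhf"),
        ):
            if col in row and pd.notna(row.get(col)):
                setattr(call, attr, int(row[col]))
        cov_pre = (
            pre_h2_coverage.loc[pg]
            if pre_h2_coverage is not None and pg in pre_h2_coverage.index
            else None
        )
        call.h2_response = _pick_h2_response(row, cov_pre)
        wl_label = NONE
        if call.wl_nearly_complete:
            if call.h2_response is None:
                wl_label = INDETERMINATE
                call.evidence.append("WL>=8 but no post/pre-H2 contrast recorded")
            else:
                wl_label = classify_wl_direction(True, call.h2_response, thresholds)
                call.evidence.append(
                    f"WL={call.wl_count}>=8, post/pre-H2 contrast {call.h2_response:+.2f}"
                )
        if wl_label not in (NONE, INDETERMINATE):
            call.roles.add(wl_label)
        if degrader_mode == "significance":
            prop_flag = bool(row.get("prop_sig", False)) if pd.notna(row.get("prop_sig", False)) else False
            but_flag = bool(row.get("but_sig", False)) if pd.notna(row.get("but_sig", False)) else False
        else:
            prop_flag = call.prop_count >= prop_count_threshold
            but_flag = call.but_count >= but_count_threshold
        deg_label = classify_degrader(prop_flag, but_flag)
        if deg_label != NONE:
            call.roles.add(deg_label)
            call.evidence.append(
                f"degrader flags prop={prop_flag} (n={call.prop_count}), "
                f"but={but_flag} (n={call.but_count})"
            )
        rows.append(
            {
                "pg_id": call.pg_id,
                "wl_count": call.wl_count,
                "wl_nearly_complete": call.wl_nearly_complete,
                "prop_count": call.prop_count,
                "but_count": call.but_count,
                "h2_response": call.h2_response,
                "wl_role": wl_label,
                "degrader_role": deg_label,
                "roles": ";".join(sorted(call.roles)) or NONE,
                "evidence": " | ".join(call.evidence),
            }
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "pg_id",
            "wl_count",
            "wl_nearly_complete",
            "prop_count",
            "but_count",
            "h2_response",
            "wl_role",
            "degrader_role",
            "roles",
            "evidence",
        ],
    )
    summary = {
        "n_pgs": len(report),
        "wl_nearly_complete": int(report["wl_nearly_complete"].sum()) if len(report) else 0,
        SAOB: int((report["wl_role"] == SAOB).sum()) if len(report) else 0,
        HOMOACETOGEN: int((report["wl_role"] == HOMOACETOGEN).sum()) if len(report) else 0,
        WL_BIDIRECTIONAL: int((report["wl_role"] == WL_BIDIRECTIONAL).sum()) if len(report) else 0,
        PROPIONATE: int((report["degrader_role"] == PROPIONATE).sum()) if len(report) else 0,
        BUTYRATE: int((report["degrader_role"] == BUTYRATE).sum()) if len(report) else 0,
        PROP_BUT: int((report["degrader_role"] == PROP_BUT).sum()) if len(report) else 0,
        "degraders": int((report["degrader_role"] != NONE).sum()) if len(report) else 0,
    }
    return report, summary


# ---------------------------------------------------------------------------
# Pathway-count table IO (cells like "24*" mark enrichment-significant counts)

_COUNT_COLUMNS = ("prop", "but", "cfp", "fad", "wl", "tca", "fdhf", "isa", "me")
_STARRED = ("prop", "but", "cfp", "fad", "tca")


def _parse_count_cell(cell) -> tuple[float, bool]:
    if pd.isna(cell) or cell == "":
        return float("nan"), False
    s = str(cell).strip()
    starred = s.endswith("*")
    if starred:
        s = s[:-1]
    return float(s), starred


def read_pathway_table(path) -> pd.DataFrame:
    """Read a per-PG pathway gene-count table.

    Columns: pg_id; thermo_post_pre / meso_post_pre contrasts; gene counts
    prop (Propanoate metabolism), but (Butanoate), cfp (Carbon fixation
    pathways), fad (Fatty acid degradation), wl (Wood-Ljungdahl), tca (TCA
    cycle), fdhf (formate dehydrogenase isoforms), isa (2-oxoisovalerate /
    dihydrolipoamide dehydrogenase alternative path), me (menaquinone
    biosynthesis).  A trailing ``*`` on a count marks the category as
    enrichment-significant; it is split into a ``<col>_sig`` boolean column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "pg_id" not in df.columns:
        raise ValidationError(f"{path}: missing pg_id column")
    out: dict[str, list] = {"pg_id": [str(x) for x in df["pg_id"]]}
    for col in ("thermo_post_pre", "meso_post_pre"):
        if col in df.columns:
            out[col] = [float(x) if pd.notna(x) and x != "" else float("nan") for x in df[col]]
    for col in _COUNT_COLUMNS:
        if col not in df.columns:
            continue
        vals, sigs = zip(*(_parse_count_cell(x) for x in df[col]))
        out[col] = list(vals)
        if col in _STARRED:
            out[f"{col}_sig"] = list(sigs)
    return pd.DataFrame(out)


def bundled_pathway_table() -> pd.DataFrame:
    """The packaged example table: WL/VFA pathway gene counts and post/pre-H2
    contrasts for 35 population genomes from biogas-upgrading reactors."""
    with resources.as_file(
        resources.files("magprofiler").joinpath("data/pathway_counts.tsv")
    ) as p:
        return read_pathway_table(p)


def load_wl_gene_config(path=None) -> dict:
    """Editable list of KEGG orthologs counted toward the WL pathway, plus
    marker genes (fhs, folD, fdhA, fdhF, menaquinone biosynthesis)."""
    if path is None:
        ref = resources.files("magprofiler").joinpath("data/wl_genes.yaml")
        with resources.as_file(ref) as p:
            with open(p) as fh:
                return yaml.safe_load(fh)
    with open(path) as fh:
        return yaml.safe_load(fh)
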