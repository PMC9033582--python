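"""Variant annotation catalog and its aggregate summaries.

The catalog is a plain table shipped with the data (no live database
queries): one row per variant with its protein change, mutation type, exon,
receptor domain, focus-formation assay (FFA) score, Ba/F3 transformation
status, OncoKB annotation snapshot, and COSMIC/GENIE case counts.

FFA scores grade 3T3 transformation 1 (no foci) to 4 (severe, anchorage-
independent foci); a score of 2 or higher is taken to mean the variant
transformed 3T3 cells. Ba/F3 transformation (IL-3-independent growth) is an
independent boolean readout.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

FFA_SCORES = (1, 2, 3, 4)
ONCOKB_GROUPS = ("oncogenic", "likely_oncogenic", "VUS")

REQUIRED_COLUMNS = ("variant_id", "ffa_score", "baf3_transforming", "oncokb")


def load_catalog(path: str | Path) -> pd.DataFrame:
    """Read and validate a catalog TSV, indexed by variant_id."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"catalog missing columns: {missing}")
    return validate_catalog(df.set_index("variant_id"))


def validate_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    bad = catalog.index[~catalog["ffa_score"].isin(FFA_SCORES)]
    if len(bad):
        raise ValueError(f"ffa_score outside 1-4 for: {bad.tolist()[:5]}")
    unknown = catalog.index[~catalog["oncokb"].isin(ONCOKB_GROUPS)]
    if len(unknown):
        raise ValueError(f"oncokb annotation must be one of {ONCOKB_GROUPS}; bad: {unknown.tolist()[:5]}")
    for col in ("cosmic_count", "genie_count"):
        if col in catalog.columns and (catalog[col] < 0).any():
            raise ValueError(f"{col} must be non-negative")
    return catalog


def ffa_distribution(catalog: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages (one decimal) of variants per FFA score."""
    validate_catalog(catalog)
    counts = catalog["ffa_score"].value_counts().reindex(FFA_SCORES, fill_value=0)
    pct = (100.0 * counts / counts.sum()).round(1)
    return pd.DataFrame({"n": counts, "pct": pct}).rename_axis("ffa_score")


def transformation_summary(catalog: pd.DataFrame) -> dict:
    """Fractions of the panel transforming 3T3 (FFA score >= 2) and Ba/F3."""
    if len(catalog) == 0:
        return {}
    validate_catalog(catalog)
    n = len(catalog)
    n_3t3 = int((catalog["ffa_score"] >= 2).sum())
    n_baf3 = int(catalog["baf3_transforming"].astype(bool).sum())
    return {
        "n_variants": n,
        "transforming_3t3": {"n": n_3t3, "pct": round(100.0 * n_3t3 / n, 1)},
        "transforming_baf3": {"n": n_baf3, "pct": round(100.0 * n_baf3 / n, 1)},
    }


def oncokb_crosstab(catalog: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FFA-score composition per OncoKB group, and the novel-oncogenic list.

    The novel-oncogenic list holds variants with strong transforming
    activity (FFA score 3 or 4) that OncoKB does not annotate as
    (likely) oncogenic, i.e. variants of unknown significance.
    """
    validate_catalog(catalog)
    crosstab = pd.crosstab(catalog["oncokb"], catalog["ffa_score"]).reindex(
        index=ONCOKB_GROUPS, columns=FFA_SCORES, fill_value=0
    )
    novel = catalog[(catalog["ffa_score"] >= 3) & (catalog["oncokb"] == "VUS")]
    return crosstab, novel
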