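"""Reference-scaled quantification of pooled competition screens.

Clone-level barcode counts are collapsed to variants, scaled against a
drug-inert reference clone carried in every sample (KRAS G12V in vitro,
GFP in vivo), and converted into relative growth inhibition under
treatment or into competition-assay proliferation trajectories.

Scaling each sample to its internal reference cancels sequencing depth, so
no separate depth normalisation is applied.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .barcode_counting import BarcodeMap, CountTable


class ConfigurationError(ValueError):
    pass


def collapse_clones(
    counts: pd.DataFrame | CountTable,
    bmap: BarcodeMap,
    mode: Literal["sum", "mean"] = "sum",
) -> pd.DataFrame:
    """Aggregate per-barcode counts into a variant x sample matrix.

    Clones are replicate measurements of one variant, so the default is to
    pool their reads (``sum``); ``mean`` is available when clone numbers are
    unequal across variants and per-clone depth should not advantage
    variants with more clones.
    """
    if isinstance(counts, CountTable):
        counts = counts.counts
    if mode not in ("sum", "mean"):
        raise ValueError(f"mode must be 'sum' or 'mean', got {mode!r}")
    shared = counts.index.intersection(bmap.barcodes)
    dropped = counts.index.difference(bmap.barcodes)
    if len(dropped):
        import logging

        logging.getLogger(__name__).warning(
            "%d counted barcodes absent from map are excluded", len(dropped)
        )
    labelled = counts.loc[shared].join(bmap.entries.loc[shared, ["variant_id"]])
    grouped = labelled.groupby("variant_id")
    return grouped.sum() if mode == "sum" else grouped.mean()


@dataclass
class ScaledAbundance:
    """Variant abundances scaled to the reference clone within each sample.

    A pseudocount is added to every count (numerator and denominator alike)
    so zero cells stay finite; it perturbs high counts negligibly and keeps
    the reference row identically 1.
    """

    values: pd.DataFrame  # variant x sample
    reference_id: str
    pseudocount: float = 0.5
    flagged_samples: list[str] = field(default_factory=list)  # reference count was 0


def scale_to_reference(
    variant_counts: pd.DataFrame,
    reference_id: str,
    pseudocount: float = 0.5,
) -> ScaledAbundance:
    """Divide each sample column by that sample's reference-clone count."""
    if reference_id not in variant_counts.index:
        raise ConfigurationError(f"reference {reference_id!r} absent from count matrix")
    ref = variant_counts.loc[reference_id]
    if not (ref > 0).any():
        raise ConfigurationError(f"reference {reference_id!r} has zero counts in every sample")
    flagged = ref.index[ref == 0].tolist()
    scaled = (variant_counts + pseudocount).div(ref + pseudocount, axis=1)
    return ScaledAbundance(scaled, reference_id, pseudocount, flagged)


@dataclass
class GrowthInhibition:
    """Relative growth under each condition, 1.0 = vehicle-equivalent.

    For each variant and condition this is the ratio of its mean scaled
    abundance across replicates to the mean under vehicle. Values above 1
    indicate relative outgrowth (resistance); near 0, depletion.
    """

    values: pd.DataFrame  # variant x condition
    replicate_cv: pd.DataFrame  # variant x condition, std/mean across replicates
    conditions: pd.DataFrame  # index: condition; e.g. afatinib/osimertinib molar doses
    vehicle: str = "vehicle"
    flagged_variants: list[str] = field(default_factory=list)  # vehicle mean 0


def relative_growth_inhibition(
    scaled: ScaledAbundance,
    samples: pd.DataFrame,
    vehicle: str = "vehicle",
) -> GrowthInhibition:
    """Average scaled abundances over replicates, then ratio to vehicle.

    ``samples`` indexes the columns of ``scaled.values`` and must carry a
    ``condition`` column; any dose columns (e.g. afatinib/osimertinib) are
    passed through into the result's condition table. Each replicate is
    scaled to its own internal reference before averaging, so depth
    differences between replicates do not weight the mean.
    """
    if "condition" not in samples.columns:
        raise ValueError("sample sheet must have a 'condition' column")
    missing = [c for c in scaled.values.columns if c not in samples.index]
    if missing:
        raise ValueError(f"samples missing from sheet: {missing[:5]}")
    condition_of = samples.loc[scaled.values.columns, "condition"]
    if vehicle not in set(condition_of):
        raise ConfigurationError(f"no sample with vehicle condition {vehicle!r}")
    grouped = scaled.values.T.groupby(condition_of)
    means = grouped.mean().T
    stds = grouped.std(ddof=1).T
    cv = stds / means
    vehicle_mean = means[vehicle]
    flagged = vehicle_mean.index[vehicle_mean == 0].tolist()
    values = means.div(vehicle_mean.replace(0, np.nan), axis=0)
    dose_cols = [c for c in samples.columns if c not in ("condition", "replicate")]
    conditions = (
        samples.drop_duplicates("condition").set_index("condition")[dose_cols]
        if dose_cols
        else pd.DataFrame(index=means.columns)
    )
    return GrowthInhibition(values, cv, conditions.loc[means.columns], vehicle, flagged)


@dataclass
class CompetitionTrajectory:
    """Pool composition over the competition-assay timepoints (days 0/2/4/7).

    ``relative_proliferation`` is the least-squares slope of log proportion
    against day, a per-variant relative fitness: variants growing faster than
    the pool average have positive slopes.
    """

    proportions: pd.DataFrame  # variant x day, columns are day numbers
    relative_proliferation: pd.Series  # per-variant slope of log-proportion vs day
    flagged_variants: list[str] = field(default_factory=list)


def competition_trajectory(counts_by_day: pd.DataFrame) -> CompetitionTrajectory:
    """Per-day pool proportions and per-variant log-linear growth slopes.

    ``counts_by_day`` is variant x day (columns are numeric days, e.g.
    0, 2, 4, 7). Days where a variant has zero reads contribute no point to
    its fit; variants absent on day 0 or observed at fewer than two
    timepoints get an undefined slope and are flagged.
    """
    days = np.asarray(counts_by_day.columns, dtype=float)
    if len(days) < 2:
        raise ValueError("need at least two timepoints")
    proportions = counts_by_day.div(counts_by_day.sum(axis=0), axis=1)
    slopes, flagged = {}, []
    day0 = counts_by_day.columns[np.argmin(days)]
    for variant, row in proportions.iterrows():
        values = row.to_numpy(dtype=float)
        usable = values > 0
        if counts_by_day.loc[variant, day0] == 0 or usable.sum() < 2:
            slopes[variant] = np.nan
            flagged.append(variant)
            continue
        slope, _ = np.polyfit(days[usable], np.log(values[usable]), 1)
        slopes[variant] = slope
    return CompetitionTrajectory(
        proportions, pd.Series(slopes, name="relative_proliferation"), flagged
    )
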