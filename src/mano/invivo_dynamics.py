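"""Heterogeneous-tumor xenograft analysis under sequential drug regimens.

Mice carrying tumors that pool many barcoded variant clones are treated
with EGFR-TKI regimens (monotherapy, simultaneous combination, sequential
switching, or rapid alternation). Tumor volume follows the caliper formula
pi/6 x large x small^2; intratumoral clone composition comes from barcode
counts of resected-tumor DNA scaled to a drug-inert GFP reference clone.
Per-variant drug sensitivity in vivo is summarised as the relative tumor
volume (RTV): the variant's proportion-weighted tumor volume in a treated
arm relative to the vehicle arm at a fixed day.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .barcode_counting import BarcodeMap
from .drug_response import DEFAULT_THRESHOLDS, Category
from .quantification import collapse_clones, scale_to_reference

logger = logging.getLogger(__name__)

_DRUG_CODES = {"A": "afatinib", "O": "osimertinib", "G": "gefitinib"}


@dataclass(frozen=True)
class Regimen:
    """Day-indexed drug schedule.

    ``schedule`` lists contiguous, non-overlapping half-open intervals
    ``(start_day, end_day, drugs)``. Days before ``start_day`` (engraftment
    period) are untreated.
    """

    name: str
    schedule: tuple[tuple[int, int, frozenset[str]], ...]
    start_day: int = 0

    def __post_init__(self) -> None:
        known = set(_DRUG_CODES.values())
        prev_end = None
        for start, end, drugs in self.schedule:
            if end <= start:
                raise ValueError(f"empty interval ({start}, {end}) in regimen {self.name}")
            if prev_end is not None and start != prev_end:
                raise ValueError(f"regimen {self.name} intervals not contiguous at day {start}")
            if set(drugs) - known:
                raise ValueError(f"unknown drugs {set(drugs) - known} in regimen {self.name}")
            prev_end = end

    @property
    def end_day(self) -> int:
        return self.schedule[-1][1]

    def drugs_on(self, day: float) -> frozenset[str]:
        for start, end, drugs in self.schedule:
            if start <= day < end:
                return drugs
        return frozenset()

    @classmethod
    def from_code(
        cls,
        code: str,
        duration: int,
        switch_day: int | None = None,
        start_day: int = 0,
        alternation_period: int = 3,
    ) -> "Regimen":
        """Build the standard regimens from their shorthand codes.

        Codes: ``vehicle``; single agents ``A``/``O``/``G``; simultaneous
        combinations ``A+O``/``G+O``; sequential switches ``AO``/``GO``/
        ``OA``/``OG`` (first drug until ``switch_day``, second thereafter);
        ``AO3`` (afatinib/osimertinib alternating every
        ``alternation_period`` days).
        """
        if duration <= start_day:
            raise ValueError("duration must exceed start_day")
        if code == "vehicle":
            return cls(code, ((start_day, duration, frozenset()),), start_day)
        if code in _DRUG_CODES:
            return cls(code, ((start_day, duration, frozenset({_DRUG_CODES[code]})),), start_day)
        if "+" in code:
            drugs = frozenset(_DRUG_CODES[c] for c in code.split("+"))
            return cls(code, ((start_day, duration, drugs),), start_day)
        if code == "AO3":
            blocks, day, idx = [], start_day, 0
            while day < duration:
                end = min(day + alternation_period, duration)
                drug = ("afatinib", "osimertinib")[idx % 2]
                blocks.append((day, end, frozenset({drug})))
                day, idx = end, idx + 1
            return cls(code, tuple(blocks), start_day)
        if len(code) == 2 and all(c in _DRUG_CODES for c in code):
            if switch_day is None or not start_day < switch_day < duration:
                raise ValueError(f"sequential regimen {code} needs start < switch_day < duration")
            first, second = (_DRUG_CODES[c] for c in code)
            return cls(
                code,
                (
                    (start_day, switch_day, frozenset({first})),
                    (switch_day, duration, frozenset({second})),
                ),
                start_day,
            )
        raise ValueError(f"unknown regimen code {code!r}")


def tumor_volume(large_mm: float | np.ndarray, small_mm: float | np.ndarray) -> float | np.ndarray:
    """Caliper tumor volume in mm^3: pi/6 x large x small^2.

    If the diameters arrive swapped (small > large) they are exchanged with
    a warning rather than rejected.
    """
    large = np.asarray(large_mm, dtype=float)
    small = np.asarray(small_mm, dtype=float)
    if (large <= 0).any() or (small <= 0).any():
        raise ValueError("diameters must be positive")
    if (small > large).any():
        logger.warning("small diameter exceeds large; swapping")
        large, small = np.maximum(large, small), np.minimum(large, small)
    volume = math.pi / 6.0 * large * small**2
    return float(volume) if volume.ndim == 0 else volume


def variant_proportions(
    counts: pd.DataFrame,
    bmap: BarcodeMap,
    reference: str = "GFP",
    pseudocount: float = 0.5,
    mode: str = "sum",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tumor variant read fractions and reference-scaled abundances.

    ``counts`` is barcode x tumor. Returns ``(proportions, scaled)``, both
    variant x tumor; proportions sum to 1 per tumor, and ``scaled`` is each
    variant's abundance relative to the reference clone in the same tumor.
    """
    variant_counts = collapse_clones(counts, bmap, mode=mode)
    if reference not in variant_counts.index:
        raise KeyError(f"reference clone {reference!r} absent from counts")
    proportions = variant_counts.div(variant_counts.sum(axis=0), axis=1)
    scaled = scale_to_reference(variant_counts, reference, pseudocount).values
    return proportions, scaled


def aggregate_proportions(
    proportions: pd.DataFrame,
    tumors: pd.DataFrame,
    geometric: bool = False,
) -> pd.DataFrame:
    """Mean variant proportions per (group, day) across the mice killed then.

    ``tumors`` indexes the columns of ``proportions`` with ``group`` and
    ``day`` columns. The arithmetic mean is the default; a geometric mean
    (with half the smallest positive value standing in for zeros) is
    available for heavily skewed compositions.
    """
    key = tumors.loc[proportions.columns, ["group", "day"]].apply(tuple, axis=1)
    grouped = proportions.T.groupby(key)
    if not geometric:
        return grouped.mean().T
    floor = proportions.to_numpy()
    positive = floor[floor > 0]
    eps = positive.min() / 2 if len(positive) else 1e-12
    return np.exp(np.log(proportions.clip(lower=eps)).T.groupby(key).mean()).T


def relative_tumor_volume(
    proportions: pd.DataFrame,
    tumors: pd.DataFrame,
    treated_group: str,
    vehicle_group: str = "vehicle",
    day: int = 15,
    min_vehicle_reads_fraction: float = 0.0,
) -> pd.Series:
    """Per-variant relative tumor volume of a treated arm vs vehicle.

    Each variant's burden in an arm is decomposed as (mean proportion) x
    (mean total volume) over the mice of that arm at the stated day, and
    RTV is the treated/vehicle ratio of these burdens. Variants absent
    from the vehicle arm (mean proportion below
    ``min_vehicle_reads_fraction`` or zero) get NaN.
    """
    meta = tumors.loc[proportions.columns]
    sel_t = (meta["group"] == treated_group) & (meta["day"] == day)
    sel_v = (meta["group"] == vehicle_group) & (meta["day"] == day)
    if not sel_t.any() or not sel_v.any():
        raise ValueError(f"no tumors for {treated_group!r} and/or {vehicle_group!r} at day {day}")
    p_t = proportions.loc[:, sel_t[sel_t].index].mean(axis=1)
    p_v = proportions.loc[:, sel_v[sel_v].index].mean(axis=1)
    v_t = meta.loc[sel_t, "volume"].mean()
    v_v = meta.loc[sel_v, "volume"].mean()
    denominator = p_v * v_v
    rtv = (p_t * v_t) / denominator.where(p_v > min_vehicle_reads_fraction)
    rtv.name = f"rtv_{treated_group}_d{day}"
    return rtv


def call_from_rtv(
    rtv: pd.Series, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
) -> pd.Series:
    """Threshold RTV into the same three categories used in vitro."""
    lo, hi = thresholds
    def categorise(value: float) -> Category:
        if np.isnan(value):
            return "undetermined"
        if value < lo:
            return "sensitive"
        if value < hi:
            return "partially_resistant"
        return "resistant"
    return rtv.map(categorise).rename("invivo_call")


def invivo_calls_and_concordance(
    rtv: pd.Series,
    invitro_calls: pd.Series,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> tuple[pd.Series, float]:
    """Compare in vivo RTV-derived calls with in vitro calls.

    Returns the in vivo call series and the concordance: the fraction of
    jointly determined variants whose categories match. Symmetric in the
    two call tables and independent of variant ordering.
    """
    invivo = call_from_rtv(rtv, thresholds)
    shared = invivo.index.intersection(invitro_calls.index)
    determined = shared[
        (invivo.loc[shared] != "undetermined") & (invitro_calls.loc[shared] != "undetermined")
    ]
    if len(determined) == 0:
        raise ValueError("no jointly determined variants to compare")
    matches = (invivo.loc[determined] == invitro_calls.loc[determined]).sum()
    return invivo, matches / len(determined)


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    pvalue: float
    n_pairs: int
    degenerate: bool = False  # zero variance of the paired differences


def paired_group_test(a: Sequence[float], b: Sequence[float]) -> PairedTestResult:
    """Two-sided paired t test between matched measurements.

    Pairs with a missing value on either side are dropped. Zero variance of
    the differences (including identical vectors) leaves the p value
    undefined and flags the result as degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if len(a) < 2:
        raise ValueError("need at least two complete pairs")
    diffs = a - b
    if np.std(diffs, ddof=1) == 0:
        return PairedTestResult(0.0 if diffs[0] == 0 else np.inf, np.nan, len(a), degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return PairedTestResult(float(t), float(p), len(a))
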