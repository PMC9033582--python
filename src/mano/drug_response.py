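"""Two-drug dose-response surfaces, sensitivity calls, Bliss synergy, 4PL fits.

The screen treats the pooled clones over a grid of afatinib x osimertinib
concentrations (default 8 x 9 log-spaced levels spanning 500 pM-50 nM and
100 pM-10 uM, i.e. 72 tested combinations, plus vehicle and monotherapy
rows). Per-variant relative growth under each condition fills a response
surface; monotherapy survival at the top tested dose drives a three-way
sensitivity call; deviation from Bliss independence over the combination
cells gives the synergy score; and a four-parameter logistic fit serves
single-agent viability validation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .quantification import GrowthInhibition

Category = Literal["sensitive", "partially_resistant", "resistant", "undetermined"]

#: survival-at-reference-dose cutoffs: < first -> sensitive,
#: < second -> partially_resistant, otherwise resistant
DEFAULT_THRESHOLDS: tuple[float, float] = (0.2, 0.5)


@dataclass(frozen=True)
class DoseGrid:
    """Concentration grid for the two-drug screen (molar units)."""

    afatinib: tuple[float, ...]
    osimertinib: tuple[float, ...]
    includes_zero: bool = True

    def __post_init__(self) -> None:
        for name in ("afatinib", "osimertinib"):
            levels = np.asarray(getattr(self, name), dtype=float)
            if len(levels) == 0 or (levels <= 0).any() or (np.diff(levels) <= 0).any():
                raise ValueError(f"{name} levels must be positive and strictly increasing")

    @classmethod
    def default(cls) -> "DoseGrid":
        return cls(
            afatinib=tuple(np.geomspace(500e-12, 50e-9, 8)),
            osimertinib=tuple(np.geomspace(100e-12, 10e-6, 9)),
        )

    @property
    def n_combinations(self) -> int:
        return len(self.afatinib) * len(self.osimertinib)

    def afatinib_axis(self) -> np.ndarray:
        """Afatinib levels with a leading zero (vehicle) when includes_zero."""
        levels = np.asarray(self.afatinib, dtype=float)
        return np.concatenate([[0.0], levels]) if self.includes_zero else levels

    def osimertinib_axis(self) -> np.ndarray:
        levels = np.asarray(self.osimertinib, dtype=float)
        return np.concatenate([[0.0], levels]) if self.includes_zero else levels

    def conditions(self) -> pd.DataFrame:
        """All (afatinib, osimertinib) cells incl. vehicle/monotherapy axes."""
        rows = [
            {"condition": dose_label(a, o), "afatinib": a, "osimertinib": o}
            for a in self.afatinib_axis()
            for o in self.osimertinib_axis()
        ]
        return pd.DataFrame(rows).set_index("condition")


def dose_label(afatinib: float, osimertinib: float) -> str:
    """Canonical condition name for a dose pair; (0, 0) is 'vehicle'."""
    if afatinib == 0 and osimertinib == 0:
        return "vehicle"
    return f"A{afatinib:.6g}_O{osimertinib:.6g}"


@dataclass
class ResponseSurface:
    """Per-variant relative growth over the dose grid.

    ``survival`` is relative growth vs vehicle (1.0 = vehicle-equivalent;
    values above 1 mean relative outgrowth). Rows follow the afatinib axis,
    columns the osimertinib axis, each including the zero dose, so
    ``survival[0, 0]`` is the vehicle cell (1.0 by construction) and the
    first row/column are the monotherapy responses.
    """

    variant_id: str
    afatinib: np.ndarray
    osimertinib: np.ndarray
    survival: np.ndarray  # shape (len(afatinib), len(osimertinib))
    missing: np.ndarray = field(default=None)  # bool mask of absent cells

    def __post_init__(self) -> None:
        self.survival = np.asarray(self.survival, dtype=float)
        if self.missing is None:
            self.missing = np.isnan(self.survival)
        if self.survival.shape != (len(self.afatinib), len(self.osimertinib)):
            raise ValueError("survival shape does not match dose axes")

    @property
    def inhibition(self) -> np.ndarray:
        """Fractional growth inhibition in [0, 1]: 1 - min(survival, 1)."""
        return 1.0 - np.clip(self.survival, 0.0, 1.0)


def build_surface(
    inhibition: GrowthInhibition,
    grid: DoseGrid,
    variant_id: str,
) -> ResponseSurface:
    """Assemble one variant's surface from the condition-wise growth table.

    Conditions are matched by their canonical dose labels. Grid cells with
    no matching condition are left as NaN and flagged in ``missing`` rather
    than imputed.
    """
    if variant_id not in inhibition.values.index:
        raise KeyError(f"variant {variant_id!r} not in growth-inhibition table")
    row = inhibition.values.loc[variant_id]
    a_axis = grid.afatinib_axis()
    o_axis = grid.osimertinib_axis()
    surface = np.full((len(a_axis), len(o_axis)), np.nan)
    for i, a in enumerate(a_axis):
        for j, o in enumerate(o_axis):
            label = dose_label(a, o) if (a or o) else inhibition.vehicle
            if label in row.index:
                surface[i, j] = row[label]
    return ResponseSurface(variant_id, a_axis, o_axis, surface)


@dataclass(frozen=True)
class SensitivityCall:
    variant_id: str
    drug: str
    category: Category
    survival_at_dose: float
    reference_dose: float


def classify_sensitivity(
    surface: ResponseSurface,
    drug: Literal["afatinib", "osimertinib"],
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
    reference_dose: float | None = None,
) -> SensitivityCall:
    """Three-way call from monotherapy survival at a reference dose.

    The default reference dose is the top tested monotherapy concentration.
    The mapping is monotone in survival s: s < lo -> sensitive,
    lo <= s < hi -> partially_resistant, s >= hi -> resistant.
    """
    lo, hi = thresholds
    if not 0 <= lo <= hi:
        raise ValueError("thresholds must satisfy 0 <= lo <= hi")
    if drug == "afatinib":
        doses, mono = surface.afatinib, surface.survival[:, 0]
    elif drug == "osimertinib":
        doses, mono = surface.osimertinib, surface.survival[0, :]
    else:
        raise ValueError(f"unknown drug {drug!r}")
    dose = float(doses[-1]) if reference_dose is None else float(reference_dose)
    # molar doses span picomolar to micromolar: match relatively, never with
    # an absolute tolerance (which would conflate nanomolar levels with zero)
    matches = np.nonzero(np.isclose(doses, dose, rtol=1e-9, atol=0.0))[0]
    if len(matches) == 0:
        raise ValueError(f"reference dose {dose} not on the {drug} axis")
    s = float(mono[matches[0]])
    if np.isnan(s):
        return SensitivityCall(surface.variant_id, drug, "undetermined", s, dose)
    if s < lo:
        category: Category = "sensitive"
    elif s < hi:
        category = "partially_resistant"
    else:
        category = "resistant"
    return SensitivityCall(surface.variant_id, drug, category, s, dose)


def cross_resistance_summary(calls: pd.DataFrame) -> dict:
    """Cross-tabulate per-variant afatinib/osimertinib calls.

    ``calls`` is indexed by variant with columns ``afatinib`` and
    ``osimertinib`` holding categories. "Nonsensitive" to a drug means
    resistant or partially resistant. Variants with an undetermined call
    for either drug are excluded from the cross-tabulation and reported.
    Percentages are rounded to one decimal.
    """
    if len(calls) == 0:
        return {"n_variants": 0, "n_undetermined": 0}
    for col in ("afatinib", "osimertinib"):
        if col not in calls.columns:
            raise ValueError(f"calls table must have an {col!r} column")
    undetermined = (calls["afatinib"] == "undetermined") | (calls["osimertinib"] == "undetermined")
    usable = calls.loc[~undetermined]
    n = len(usable)
    a_non = usable["afatinib"] != "sensitive"
    o_non = usable["osimertinib"] != "sensitive"
    a_res = usable["afatinib"] == "resistant"
    o_res = usable["osimertinib"] == "resistant"

    def pct(k: int, total: int) -> float:
        return round(100.0 * k / total, 1) if total else float("nan")

    any_non = int((a_non | o_non).sum())
    both_res = int((a_res & o_res).sum())
    both_non = int((a_non & o_non).sum())
    n_a_non = int(a_non.sum())
    n_o_non = int(o_non.sum())
    a_non_o_sens = int((a_non & ~o_non).sum())
    o_non_a_sens = int((o_non & ~a_non).sum())
    summary = {
        "n_variants": n,
        "n_undetermined": int(undetermined.sum()),
        "nonsensitive_any": {"n": any_non, "pct": pct(any_non, n)},
        "resistant_both": {"n": both_res, "pct": pct(both_res, n)},
        "nonsensitive_both": {"n": both_non, "pct": pct(both_non, n)},
        "afatinib_nonsensitive": {
            "n": n_a_non,
            "osimertinib_sensitive_n": a_non_o_sens,
            "osimertinib_sensitive_pct": pct(a_non_o_sens, n_a_non),
        },
        "osimertinib_nonsensitive": {
            "n": n_o_non,
            "afatinib_sensitive_n": o_non_a_sens,
            "afatinib_sensitive_pct": pct(o_non_a_sens, n_o_non),
        },
    }
    # conservation: the four exclusive cells plus undetermined cover everything
    sens_both = n - any_non
    assert sens_both + a_non_o_sens + o_non_a_sens + both_non + int(undetermined.sum()) == len(calls)
    return summary


@dataclass
class SynergyResult:
    """Bliss-excess synergy over the combination cells, in percentage points.

    Per cell the score is 100 x (observed inhibition - Bliss expectation
    E_a + E_o - E_a.E_o); computed equivalently in survival space as
    100 x (s_a.s_o - s_obs) so that surfaces with exactly multiplicative
    survival score exactly zero. Positive means more inhibition than
    independent drug action predicts.
    """

    variant_id: str
    scores: np.ndarray  # combination cells only, shape (n_afat, n_osi)
    mean_score: float
    clipped_cells: int = 0


def bliss_synergy(surface: ResponseSurface) -> SynergyResult:
    """Score deviation from Bliss independence across combination cells."""
    if not (surface.afatinib[0] == 0 and surface.osimertinib[0] == 0):
        raise ValueError("surface must include monotherapy axes (zero doses)")
    raw = surface.survival
    outside = (raw < 0) | (raw > 1)
    n_clipped = int(np.nansum(outside))
    if n_clipped:
        warnings.warn(
            f"{surface.variant_id}: {n_clipped} cells outside [0,1] clipped for Bliss",
            stacklevel=2,
        )
    s = np.clip(raw, 0.0, 1.0)
    s_a = s[1:, 0][:, None]  # monotherapy survivals
    s_o = s[0, 1:][None, :]
    observed = s[1:, 1:]
    scores = 100.0 * (s_a * s_o - observed)
    mean = float(np.nanmean(scores))
    return SynergyResult(surface.variant_id, scores, mean, n_clipped)


@dataclass
class FourPLFit:
    """Four-parameter logistic dose-response fit."""

    top: float
    bottom: float
    ic50: float
    hill: float
    rss: float
    converged: bool = True
    in_range: bool = True

    def predict(self, dose: np.ndarray) -> np.ndarray:
        return four_pl(np.asarray(dose, dtype=float), self.top, self.bottom, self.ic50, self.hill)


def four_pl(dose: np.ndarray, top: float, bottom: float, ic50: float, hill: float) -> np.ndarray:
    """response = bottom + (top - bottom) / (1 + (dose/ic50)^hill)."""
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


def fit_4pl(doses: np.ndarray, response: np.ndarray, n_starts: int = 8) -> FourPLFit:
    """Least-squares 4PL fit with deterministic multi-start on the IC50.

    IC50 starting points are log-spaced from a tenth of the lowest to ten
    times the highest tested dose; the start with the lowest residual sum
    of squares wins. A fit whose IC50 lands outside the tested range is
    kept but flagged ``in_range=False``; total non-convergence returns a
    flagged fit with infinite RSS.
    """
    doses = np.asarray(doses, dtype=float)
    response = np.asarray(response, dtype=float)
    if len(doses) < 4:
        raise ValueError("need at least 4 dose levels")
    if (doses <= 0).any():
        raise ValueError("doses must be positive")
    top0, bottom0 = float(response.max()), float(response.min())
    seeds = np.geomspace(doses.min() / 10.0, doses.max() * 10.0, n_starts)
    best: FourPLFit | None = None
    for ic50_seed in seeds:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    four_pl,
                    doses,
                    response,
                    p0=[top0, bottom0, ic50_seed, 1.0],
                    bounds=([-np.inf, -np.inf, doses.min() / 1e4, 0.05],
                            [np.inf, np.inf, doses.max() * 1e4, 20.0]),
                    maxfev=5000,
                )
        except RuntimeError:
            continue
        rss = float(np.sum((response - four_pl(doses, *popt)) ** 2))
        if best is None or rss < best.rss:
            top, bottom, ic50, hill = (float(v) for v in popt)
            best = FourPLFit(
                top, bottom, ic50, hill, rss,
                in_range=bool(doses.min() <= ic50 <= doses.max()),
            )
    if best is None:
        return FourPLFit(np.nan, np.nan, np.nan, np.nan, np.inf, converged=False)
    return best
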