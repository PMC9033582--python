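"""Synthetic pooled-screen data with known ground truth.

The generator emulates the statistical structure of a pooled barcoded
variant competition experiment: a panel of clones (each variant carried by
up to three independently barcoded clones, mixed equally at day 0) grows
exponentially with a clone-specific rate, drugs scale the growth rate
through per-drug Hill curves combined multiplicatively (Bliss-independent
unless an interaction term is injected), and sequencing reads are drawn
multinomially from Dirichlet-perturbed clone proportions to mimic PCR and
subsampling overdispersion. Every simulation emits its ground truth
alongside the observable data, so recovery by the analysis stack can be
checked quantitatively.

Clone archetypes mirror the qualitative sensitivity classes seen in
EGFR-TKI screens: sensitive to both drugs (L858R-like), resistant to both
(exon-20-insertion-like, which also proliferate fastest), resistant to
afatinib only (T790M-like), and resistant to osimertinib only
(L718V/V802F-like). Drug-inert reference clones (KRAS_G12V-like for the
in vitro screens, GFP-like for tumors) are always included.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .barcode_counting import BarcodeContext, BarcodeMap, CountTable
from .drug_response import DoseGrid, dose_label
from .invivo_dynamics import Regimen, tumor_volume

ARCHETYPES = (
    "sensitive_both",
    "resistant_both",
    "afatinib_resistant",
    "osimertinib_resistant",
)

#: approximate composition of the screened panel by sensitivity class
DEFAULT_ARCHETYPE_MIX = (0.82, 0.09, 0.01, 0.08)

#: effective drug exposures used for tumor simulations (molar)
INVIVO_CONC = {"afatinib": 10e-9, "gefitinib": 10e-9, "osimertinib": 100e-9}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b


@dataclass(frozen=True)
class HillParams:
    """Single-drug Hill inhibition: I(c) = imax / (1 + (ic50/c)^hill)."""

    ic50: float
    hill: float = 2.0
    imax: float = 1.0

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("ic50 must be positive")
        if not 0 <= self.imax <= 1:
            raise ValueError("imax must lie in [0, 1]")

    def inhibition(self, conc: float) -> float:
        if conc <= 0:
            return 0.0
        return self.imax / (1.0 + (self.ic50 / conc) ** self.hill)


@dataclass(frozen=True)
class CloneModel:
    """Growth and two-drug sensitivity parameters of one barcoded clone set."""

    variant_id: str
    barcodes: tuple[str, ...]
    base_growth_rate: float  # per-day log growth, drug-free
    drug_params: Mapping[str, HillParams]
    epsilon: float = 0.0  # Bliss deviation: extra inhibition under >=2 drugs
    archetype: str = "sensitive_both"
    initial_weight: float = 1.0  # relative initial abundance in the pool

    def survival(self, conc: Mapping[str, float]) -> float:
        """Multiplicative growth-rate survival factor under the given doses.

        With ``epsilon == 0`` the combined survival is exactly the product
        of the single-drug survivals (Bliss independence); a positive
        epsilon multiplies in an extra (1 - epsilon) whenever at least two
        drugs are present.
        """
        s = 1.0
        active = 0
        for drug, c in conc.items():
            if c > 0 and drug in self.drug_params:
                s *= 1.0 - self.drug_params[drug].inhibition(c)
                active += 1
        if active >= 2:
            s *= 1.0 - self.epsilon
        return max(s, 0.0)


def _archetype_params(archetype: str, rng: np.random.Generator) -> dict[str, HillParams]:
    """Hill parameters for one clone of the given archetype, with jitter."""
    def jitter(x: float) -> float:
        return float(x * rng.lognormal(0.0, 0.2))

    sens_afat = lambda: HillParams(jitter(2e-9), 2.0, 1.0)
    sens_osi = lambda: HillParams(jitter(20e-9), 2.0, 1.0)
    sens_gef = lambda: HillParams(jitter(3e-9), 2.0, 1.0)
    res = lambda: HillParams(1e-9, 1.0, 0.1)  # ~90% of growth retained
    if archetype == "sensitive_both":
        return {"afatinib": sens_afat(), "osimertinib": sens_osi(), "gefitinib": sens_gef()}
    if archetype == "resistant_both":
        return {"afatinib": res(), "osimertinib": res(), "gefitinib": res()}
    if archetype == "afatinib_resistant":
        # first/second-generation TKI resistance: gefitinib tracks afatinib
        return {"afatinib": res(), "osimertinib": sens_osi(), "gefitinib": res()}
    if archetype == "osimertinib_resistant":
        return {"afatinib": sens_afat(), "osimertinib": res(), "gefitinib": sens_gef()}
    raise ValueError(f"unknown archetype {archetype!r}")


def _random_barcodes(n: int, length: int, rng: np.random.Generator, taken: set[str]) -> list[str]:
    out: list[str] = []
    for _ in range(n):
        for _attempt in range(100):
            bc = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
            if bc not in taken:
                taken.add(bc)
                out.append(bc)
                break
        else:
            raise RuntimeError("could not draw a unique barcode in 100 attempts")
    return out


def make_panel(
    n_variants: int = 282,
    archetype_mix: Sequence[float] = DEFAULT_ARCHETYPE_MIX,
    seed: int = 0,
    clones_per_variant: int = 3,
    barcode_length: int = 10,
    include_references: bool = True,
    epsilon: float = 0.0,
) -> list[CloneModel]:
    """Deterministic panel of clone models for a seed.

    Archetype counts follow ``archetype_mix`` by largest-remainder rounding.
    Drug-free growth rates are drawn around 0.7/day (roughly one doubling
    per day in suspension culture); dual-resistant clones grow faster
    (0.85/day) to mirror the strong proliferative advantage of exon-20
    insertions in competition. Reference clones (KRAS_G12V, GFP) are
    drug-inert with slightly below-average growth.
    """
    mix = np.asarray(archetype_mix, dtype=float)
    if len(mix) != len(ARCHETYPES) or mix.min() < 0 or not np.isclose(mix.sum(), 1.0, atol=1e-6):
        raise ValueError("archetype_mix must be 4 non-negative fractions summing to 1")
    rng = np.random.default_rng(seed)
    raw = mix * n_variants
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: n_variants - counts.sum()]:
        counts[i] += 1
    taken: set[str] = set()
    panel: list[CloneModel] = []
    idx = 0
    for archetype, k in zip(ARCHETYPES, counts):
        for _ in range(k):
            idx += 1
            growth_mu = 0.85 if archetype == "resistant_both" else 0.7
            panel.append(
                CloneModel(
                    variant_id=f"{archetype.upper()[:3]}_{idx:04d}",
                    barcodes=tuple(_random_barcodes(clones_per_variant, barcode_length, rng, taken)),
                    base_growth_rate=float(max(rng.normal(growth_mu, 0.05), 0.05)),
                    drug_params=_archetype_params(archetype, rng),
                    epsilon=epsilon,
                    archetype=archetype,
                )
            )
    if include_references:
        inert = {d: HillParams(1e-9, 1.0, 0.0) for d in INVIVO_CONC}
        # KRAS_G12V transforms the assay cells and keeps pace with the pool;
        # the GFP clone is non-transforming and barely proliferates.
        for ref, growth_mu in (("KRAS_G12V", 0.6), ("GFP", 0.1)):
            panel.append(
                CloneModel(
                    variant_id=ref,
                    barcodes=tuple(_random_barcodes(clones_per_variant, barcode_length, rng, taken)),
                    base_growth_rate=float(max(rng.normal(growth_mu, 0.03), 0.02)),
                    drug_params=inert,
                    archetype="reference",
                )
            )
    return panel


def make_regimen_panel(
    seed: int = 0,
    n_sensitive: int = 20,
    dominant_weight: float = 2.0,
    n_dual_resistant: int = 2,
    dual_resistant_fraction: float = 1e-4,
) -> list[CloneModel]:
    """Panel for sequential-regimen comparisons.

    One dominant afatinib-resistant / osimertinib-sensitive clone sits in a
    background of drug-sensitive clones, plus rare pre-existing
    dual-resistant subclones at realistic pre-treatment frequencies
    (~1e-4). This is the composition in which switching order matters:
    the dominant clone expands under whichever phase contains afatinib.
    """
    rng = np.random.default_rng(seed)
    taken: set[str] = set()
    panel: list[CloneModel] = []

    def add(variant_id: str, archetype: str, weight: float, growth_mu: float = 0.7) -> None:
        panel.append(
            CloneModel(
                variant_id=variant_id,
                barcodes=tuple(_random_barcodes(3, 10, rng, taken)),
                base_growth_rate=float(max(rng.normal(growth_mu, 0.05), 0.05)),
                drug_params=_archetype_params(archetype, rng)
                if archetype != "reference"
                else {d: HillParams(1e-9, 1.0, 0.0) for d in INVIVO_CONC},
                archetype=archetype,
                initial_weight=weight,
            )
        )

    for i in range(n_sensitive):
        add(f"SEN_{i:03d}", "sensitive_both", 1.0)
    add("AFA_RES_DOMINANT", "afatinib_resistant", dominant_weight)
    total_weight = n_sensitive + dominant_weight + 1.0  # + GFP below
    for i in range(n_dual_resistant):
        add(f"DUAL_{i:02d}", "resistant_both", dual_resistant_fraction * total_weight)
    add("GFP", "reference", 1.0, growth_mu=0.1)
    return panel


def panel_to_map(panel: Sequence[CloneModel]) -> BarcodeMap:
    rows = [
        {"barcode": bc, "variant_id": clone.variant_id, "clone_index": i + 1}
        for clone in panel
        for i, bc in enumerate(clone.barcodes)
    ]
    refs = frozenset(c.variant_id for c in panel if c.archetype == "reference")
    return BarcodeMap(pd.DataFrame(rows).set_index("barcode"), refs)


def _clone_barcode_frame(panel: Sequence[CloneModel]) -> pd.DataFrame:
    """One row per barcode with its clone's index into the panel."""
    rows = [
        {"barcode": bc, "clone": i}
        for i, clone in enumerate(panel)
        for bc in clone.barcodes
    ]
    return pd.DataFrame(rows)


@dataclass
class ScreenSimulation:
    panel: list[CloneModel]
    counts: CountTable
    truth: pd.DataFrame  # variant x condition: true relative survival vs vehicle
    barcode_map: BarcodeMap
    grid: DoseGrid


def simulate_screen(
    panel: Sequence[CloneModel],
    grid: DoseGrid | None = None,
    days: float = 4.0,
    depth: int = 1_000_000,
    overdispersion: float | None = 2000.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> ScreenSimulation:
    """Simulate the in vitro two-drug screen over the full dose grid.

    Clones start at equal abundance (scaled by their ``initial_weight``),
    grow as N(t) = N(0) * exp(g * s(c) * t) with the survival factor s(c)
    from the clone's Hill parameters, and are sequenced to ``depth`` reads
    per sample. ``overdispersion`` is a Dirichlet concentration scalar
    (None for pure multinomial sampling). The emitted truth table holds
    each variant's true relative survival exp(g * (s - 1) * days), the
    quantity the reference-scaled analysis estimates.
    """
    grid = grid or DoseGrid.default()
    rng = np.random.default_rng(seed)
    conditions = grid.conditions()
    bc_frame = _clone_barcode_frame(panel)
    clone_of_bc = bc_frame["clone"].to_numpy()
    growth = np.array([c.base_growth_rate for c in panel])
    weights = np.array([c.initial_weight / len(c.barcodes) for c in panel])

    columns: dict[str, np.ndarray] = {}
    sample_rows = []
    truth_cols = {}
    for condition, row in conditions.iterrows():
        conc = {"afatinib": row["afatinib"], "osimertinib": row["osimertinib"]}
        s = np.array([c.survival(conc) for c in panel])
        mass = weights * np.exp(growth * s * days)
        probs = mass[clone_of_bc]
        probs = probs / probs.sum()
        truth_cols[condition] = np.exp(growth * (s - 1.0) * days)
        for rep in range(1, n_replicates + 1):
            if overdispersion is not None:
                p = rng.dirichlet(np.maximum(probs * overdispersion, 1e-12))
            else:
                p = probs
            sample_id = f"{condition}_r{rep}"
            columns[sample_id] = rng.multinomial(depth, p)
            sample_rows.append(
                {
                    "sample": sample_id,
                    "condition": condition,
                    "afatinib": row["afatinib"],
                    "osimertinib": row["osimertinib"],
                    "replicate": rep,
                }
            )
    counts = CountTable(
        pd.DataFrame(columns, index=bc_frame["barcode"]),
        pd.Series(0, index=list(columns)),
        pd.Series(0, index=list(columns)),
        pd.DataFrame(sample_rows).set_index("sample"),
    )
    truth = pd.DataFrame(truth_cols, index=[c.variant_id for c in panel])
    return ScreenSimulation(list(panel), counts, truth, panel_to_map(panel), grid)


@dataclass
class InVivoSimulation:
    panel: list[CloneModel]
    regimen: Regimen
    volumes: pd.DataFrame  # mouse_id, group, day, large, small, volume
    counts: pd.DataFrame  # barcode x tumor_id, resected tumors only
    tumors: pd.DataFrame  # index tumor_id: mouse_id, group, day, volume
    truth_masses: pd.DataFrame  # clone masses (variant x tumor_id) at resection
    barcode_map: BarcodeMap


def simulate_invivo(
    panel: Sequence[CloneModel],
    regimen: Regimen,
    n_mice_per_kill: int = 3,
    kill_days: Sequence[int] = (15,),
    measurement_days: Sequence[int] | None = None,
    depth: int = 100_000,
    overdispersion: float | None = 200.0,
    seed: int = 0,
    death_rate: float = 0.3,
    growth_scale: float = 0.4,
    drug_conc: Mapping[str, float] = INVIVO_CONC,
    initial_volume_mm3: float = 1.5,
    volume_noise_sd: float = 0.05,
    eccentricity_sd: float = 0.1,
) -> InVivoSimulation:
    """Simulate one treatment arm of the heterogeneous-tumor experiment.

    Clone masses follow day-by-day exponential dynamics with net rate
    (g_invivo + death_rate) * s - death_rate, where g_invivo =
    growth_scale * base growth rate: a fully inhibited clone (s = 0)
    regresses at ``death_rate`` per day while an untreated one (s = 1)
    grows at its in vivo rate. The drug set on each day comes from the
    regimen schedule; exposure uses fixed effective concentrations.
    Total mass maps to a caliper volume (sphere-equivalent diameter split
    into large/small by a lognormal eccentricity, plus measurement noise);
    barcode counts at each kill day are Dirichlet-multinomial draws from
    the clone masses.
    """
    rng = np.random.default_rng(seed)
    bc_frame = _clone_barcode_frame(panel)
    clone_of_bc = bc_frame["clone"].to_numpy()
    weights = np.array([c.initial_weight for c in panel])
    weights = weights / weights.sum()
    g = np.array([c.base_growth_rate for c in panel]) * growth_scale
    end = regimen.end_day
    if max(kill_days) > end:
        raise ValueError("kill_days extend past the regimen schedule")
    if measurement_days is None:
        measurement_days = sorted(set(list(range(0, end + 1, 3)) + list(kill_days)))

    # pre-compute per-day survival factors (regimen is piecewise constant)
    day_survival = np.empty((end, len(panel)))
    for day in range(end):
        drugs = regimen.drugs_on(day)
        conc = {d: (drug_conc[d] if d in drugs else 0.0) for d in drug_conc}
        day_survival[day] = [c.survival(conc) for c in panel]

    vol_rows, count_cols, tumor_rows, truth_cols = [], {}, [], {}
    mouse_no = 0
    for kill_day in kill_days:
        for _ in range(n_mice_per_kill):
            mouse_no += 1
            mouse_id = f"{regimen.name}_m{mouse_no:02d}"
            mass = weights * rng.lognormal(0.0, 0.05, len(panel))
            mass0 = mass.sum()
            masses_by_day = {0: mass.copy()}
            for day in range(kill_day):
                net = (g + death_rate) * day_survival[day] - death_rate
                mass = mass * np.exp(net)
                masses_by_day[day + 1] = mass.copy()
            for day in [d for d in measurement_days if d <= kill_day]:
                true_volume = initial_volume_mm3 * masses_by_day[day].sum() / mass0
                observed = true_volume * rng.lognormal(0.0, volume_noise_sd)
                ratio = rng.lognormal(0.0, eccentricity_sd)  # large/small
                ratio = max(ratio, 1.0 / ratio)
                d_eq = (6.0 * observed / np.pi) ** (1.0 / 3.0)
                small = d_eq / ratio ** (1.0 / 3.0)
                large = ratio ** (2.0 / 3.0) * d_eq
                vol_rows.append(
                    {
                        "mouse_id": mouse_id,
                        "group": regimen.name,
                        "day": day,
                        "large": large,
                        "small": small,
                        "volume": tumor_volume(large, small),
                    }
                )
            tumor_id = f"{mouse_id}_d{kill_day}"
            final = masses_by_day[kill_day]
            probs = (final / final.sum())[clone_of_bc]
            probs = probs / np.array([len(panel[i].barcodes) for i in clone_of_bc])
            probs = probs / probs.sum()
            if overdispersion is not None:
                probs = rng.dirichlet(np.maximum(probs * overdispersion, 1e-12))
            count_cols[tumor_id] = rng.multinomial(depth, probs)
            truth_cols[tumor_id] = final
            tumor_rows.append(
                {
                    "tumor_id": tumor_id,
                    "mouse_id": mouse_id,
                    "group": regimen.name,
                    "day": kill_day,
                    "volume": vol_rows[-1]["volume"],
                }
            )
    return InVivoSimulation(
        list(panel),
        regimen,
        pd.DataFrame(vol_rows),
        pd.DataFrame(count_cols, index=bc_frame["barcode"]),
        pd.DataFrame(tumor_rows).set_index("tumor_id"),
        pd.DataFrame(truth_cols, index=[c.variant_id for c in panel]),
        panel_to_map(panel),
    )


def emit_fastq(
    counts: Mapping[str, int] | pd.Series,
    r1_path: str | Path,
    r2_path: str | Path | None = None,
    context: BarcodeContext | None = None,
    read_length: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
) -> int:
    """Write paired FASTQ files embedding each barcode ``counts[bc]`` times.

    Each read places the cassette (flank5 + barcode + flank3) at a random
    offset inside random background sequence; substitution errors are
    applied at ``error_rate`` per base. Mate 2 is the reverse complement of
    the mate-1 template with independent errors. Output is gzipped when the
    path ends in ``.gz``. Returns the number of read pairs written.
    """
    ctx = context or BarcodeContext()
    counts = pd.Series(counts, dtype=int)
    span = ctx.span
    if read_length < span:
        raise ValueError(f"read_length {read_length} shorter than cassette span {span}")
    rng = np.random.default_rng(seed)
    n = int(counts.sum())
    barcodes = np.repeat(counts.index.to_numpy(), counts.to_numpy())
    rng.shuffle(barcodes)

    template = _BASES[rng.integers(0, 4, (n, read_length))]
    offsets = rng.integers(0, read_length - span + 1, n)
    if n:
        bc_bytes = np.frombuffer(
            "".join(barcodes).encode(), dtype=np.uint8
        ).reshape(n, ctx.barcode_length)
        f5 = np.frombuffer(ctx.flank5.encode(), dtype=np.uint8)
        f3 = np.frombuffer(ctx.flank3.encode(), dtype=np.uint8)
        cassettes = np.hstack(
            [np.tile(f5, (n, 1)), bc_bytes, np.tile(f3, (n, 1))]
        )
        template[np.arange(n)[:, None], offsets[:, None] + np.arange(span)] = cassettes

    def with_errors(mat: np.ndarray) -> np.ndarray:
        if error_rate <= 0:
            return mat
        out = mat.copy()
        mask = rng.random(mat.shape) < error_rate
        base_index = np.empty(256, dtype=np.uint8)
        for j, b in enumerate(_BASES):
            base_index[b] = j
        shifted = (base_index[out[mask]] + rng.integers(1, 4, mask.sum())) % 4
        out[mask] = _BASES[shifted]
        return out

    r1 = with_errors(template)
    r2 = with_errors(_COMP[template][:, ::-1])

    def write(path: str | Path, mat: np.ndarray, mate: int) -> None:
        opener = gzip.open if str(path).endswith(".gz") else open
        qual = "I" * read_length
        rows = np.ascontiguousarray(mat).view(f"S{read_length}").ravel()
        with opener(path, "wt") as fh:
            for i, row in enumerate(rows):
                fh.write(f"@read{i}/{mate}\n{row.decode()}\n+\n{qual}\n")

    write(r1_path, r1, 1)
    if r2_path is not None:
        write(r2_path, r2, 2)
    return n


def make_catalog(seed: int = 0, n_variants: int = 357) -> pd.DataFrame:
    """Synthetic variant annotation catalog.

    Emulates the schema and marginal composition of the screened panel's
    annotation table: FFA scores split 213/29/50/65 across 1-4 (scaled for
    other panel sizes), 282 of 357 variants transforming Ba/F3 (every
    3T3-transforming variant plus a slice of the FFA-negative ones), and an
    OncoKB snapshot in which 26 strongly transforming variants (score 3-4)
    are unannotated (VUS) - the novel-oncogenic candidates. Identifiers and
    per-variant annotations are randomised; the marginals are fixed.
    """
    rng = np.random.default_rng(seed)
    base = np.array([213, 29, 50, 65])
    raw = base * n_variants / base.sum()
    score_counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - score_counts))[: n_variants - score_counts.sum()]:
        score_counts[i] += 1
    scores = np.repeat([1, 2, 3, 4], score_counts)
    rng.shuffle(scores)

    n_baf3 = round(282 * n_variants / 357)
    baf3 = scores >= 2  # transforming 3T3 implies Ba/F3 transformation here
    negatives = np.nonzero(~baf3)[0]
    extra = rng.choice(negatives, size=max(n_baf3 - int(baf3.sum()), 0), replace=False)
    baf3[extra] = True

    oncokb = np.where(scores >= 3, "oncogenic", "VUS").astype(object)
    high = np.nonzero(scores >= 3)[0]
    n_novel = min(round(26 * n_variants / 357), len(high))
    novel = rng.choice(high, size=n_novel, replace=False)
    oncokb[novel] = "VUS"
    likely = rng.choice(
        np.setdiff1d(high, novel), size=len(np.setdiff1d(high, novel)) // 3, replace=False
    )
    oncokb[likely] = "likely_oncogenic"
    some_mild = np.nonzero(scores == 2)[0]
    if len(some_mild):
        oncokb[rng.choice(some_mild, size=len(some_mild) // 2, replace=False)] = "likely_oncogenic"

    exons = rng.choice(np.arange(18, 29), size=n_variants, p=_exon_weights())
    domains = np.where(exons <= 23, "TKD", "RD")
    mutation_type = rng.choice(
        ["missense", "insertion", "deletion", "compound"], size=n_variants, p=[0.7, 0.1, 0.1, 0.1]
    )
    cosmic = rng.negative_binomial(0.4, 0.05, n_variants)
    return pd.DataFrame(
        {
            "variant_id": [f"EGFR_VAR{i:04d}" for i in range(n_variants)],
            "protein_change": [f"X{i}Y" for i in rng.integers(100, 900, n_variants)],
            "mutation_type": mutation_type,
            "exon": exons,
            "domain": domains,
            "ffa_score": scores,
            "baf3_transforming": baf3,
            "oncokb": oncokb,
            "cosmic_count": cosmic,
            "genie_count": rng.poisson(np.maximum(cosmic * 0.5, 0.1)),
        }
    ).set_index("variant_id")


def _exon_weights() -> np.ndarray:
    w = np.array([2, 3, 4, 3, 1, 1, 1, 1, 1, 1, 1], dtype=float)  # exons 18-28
    return w / w.sum()


def make_call_table(seed: int = 0) -> pd.DataFrame:
    """Synthetic per-variant sensitivity call table for the two-drug screen.

    Fixed composition over 282 Ba/F3-transforming variants: 232 sensitive
    to both drugs, 4 afatinib-nonsensitive but osimertinib-sensitive, 25
    osimertinib-nonsensitive but afatinib-sensitive, and 21 nonsensitive to
    both of which 3 are fully resistant to both. Ordering and the
    partial/full split within the free cells are randomised.
    """
    rng = np.random.default_rng(seed)

    def some(n: int, choices: Sequence[tuple[str, str]]) -> list[tuple[str, str]]:
        return [choices[i] for i in rng.integers(0, len(choices), n)]

    rows: list[tuple[str, str]] = []
    rows += [("sensitive", "sensitive")] * 232
    rows += some(4, [("resistant", "sensitive"), ("partially_resistant", "sensitive")])
    rows += some(25, [("sensitive", "resistant"), ("sensitive", "partially_resistant")])
    rows += [("resistant", "resistant")] * 3
    rows += some(
        18,
        [
            ("partially_resistant", "partially_resistant"),
            ("partially_resistant", "resistant"),
            ("resistant", "partially_resistant"),
        ],
    )
    order = rng.permutation(len(rows))
    table = pd.DataFrame(
        [rows[i] for i in order],
        columns=["afatinib", "osimertinib"],
        index=[f"EGFR_VAR{i:04d}" for i in range(len(rows))],
    )
    table.index.name = "variant_id"
    return table


def make_rtv_table(
    invitro_calls: pd.Series,
    n_variants: int = 34,
    n_discordant: int = 2,
    seed: int = 0,
    thresholds: tuple[float, float] = (0.2, 0.5),
) -> pd.Series:
    """Synthetic per-variant relative-tumor-volume values for a treated arm.

    RTVs are drawn inside the band matching each variant's in vitro call,
    except for ``n_discordant`` variants pushed one category away, emulating
    the imperfect in vivo/in vitro agreement of a real screen.
    """
    rng = np.random.default_rng(seed)
    lo, hi = thresholds
    chosen = invitro_calls.iloc[: n_variants]
    bands = {
        "sensitive": (lo * 0.1, lo * 0.9),
        "partially_resistant": (lo * 1.05, hi * 0.95),
        "resistant": (hi * 1.05, hi * 3.0),
    }
    discordant = set(rng.choice(n_variants, size=n_discordant, replace=False))
    values = {}
    shift = {"sensitive": "partially_resistant", "partially_resistant": "resistant",
             "resistant": "sensitive"}
    for i, (variant, call) in enumerate(chosen.items()):
        band = bands[shift[call] if i in discordant else call]
        values[variant] = float(rng.uniform(*band))
    return pd.Series(values, name="rtv")
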