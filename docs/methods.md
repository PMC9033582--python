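# Methods

## The assay this package analyses

A pooled competition screen mixes hundreds of variant-expressing clones in
one culture or tumor. Each clone carries a random 10-bp DNA barcode
integrated with its transgene inside the fixed cassette
`5'-CTAGACTGCC-XXXXXXXXXX-GGATCACTCT-3'`; up to three independently
barcoded clones per variant provide built-in triplicates. After growth with
or without drug, the barcodes are PCR-amplified from genomic DNA and
sequenced (150-bp paired-end reads), and read counts stand in for clone
abundances. Because every sample carries a drug-inert reference clone
(KRAS G12V in suspension-culture screens, a GFP clone in tumors), scaling
counts to the reference inside each sample cancels sequencing depth and
library-size effects, and the ratio of reference-scaled abundance under
treatment to that under vehicle estimates each variant's relative growth
under drug.

## Barcode extraction

Reads are scanned for the cassette: mate 1 then mate 2, forward then
reverse complement, first hit wins. Each flank may be matched exactly
(default) or within a configurable Hamming distance; when mismatches are
allowed, every admissible placement is enumerated and the leftmost wins,
so counting is deterministic. No mismatches are ever tolerated inside the
barcode itself: any 10-mer is a priori a valid barcode, so a read whose
extracted barcode is not in the map is tallied as *unassigned* rather than
error-corrected. Reads with no cassette placement are tallied as
*no_context*. The three bins partition the input exactly
(assigned + unassigned + no_context = read pairs processed), an invariant
asserted at run time. A minimum mean base quality over the barcode window
can be required; it is off by default because the counting statistics are
dominated by barcode-identity errors, not quality-callable ones. At a
sequencing error rate of 0.1% per base and flank tolerance 1, the expected
loss channel is an error inside the 10-bp barcode, 1 − 0.999¹⁰ ≈ 1% of
reads, which land in the unassigned bin.

## Quantification

Clone-level counts are collapsed to variants (sum by default; clones are
replicate measurements of one variant). A pseudocount (default 0.5) is
added to every count before dividing each sample by its reference-clone
count, keeping zero cells finite, perturbing high counts negligibly, and
leaving the reference row identically 1. Relative growth under a condition
is mean reference-scaled abundance across replicates divided by the
vehicle mean; each replicate is scaled to its own internal reference
*before* averaging, so depth differences between replicates do not weight
the mean (the alternative ordering — average raw counts, then scale —
differs when depth varies; the chosen ordering is recorded in the run
manifest). No separate depth normalisation is applied: the reference ratio
already cancels depth, which the scale-invariance tests verify.

Competition assays (days 0/2/4/7) are summarised as per-day pool
proportions and a per-variant least-squares slope of log proportion
against day — a relative-fitness estimate. Days with zero reads contribute
no point; variants absent at day 0 are flagged rather than fit.

## Dose–response surfaces, calls, and synergy

The screen's condition grid defaults to 8 log-spaced afatinib levels
(500 pM–50 nM) × 9 osimertinib levels (100 pM–10 µM) — 72 combinations —
plus vehicle and the two monotherapy axes. Grids are user-configurable
because published combination designs vary and the printed description of
the design is not a full enumeration. Surfaces index relative growth
("survival", 1 = vehicle-like) by the two dose axes including zero; cells
without data are flagged, never imputed.

Sensitivity calls threshold monotherapy survival at the top tested dose:
survival < 0.2 → sensitive, < 0.5 → partially resistant, ≥ 0.5 →
resistant. The cutoffs are configurable and recorded; the mapping is
monotone in survival by construction. "Nonsensitive" in the
cross-resistance summary means resistant or partially resistant. In vivo
calls reuse the same cutoffs on the relative tumor volume for
comparability.

Bliss synergy scores each combination cell as
100 × (observed inhibition − (E_a + E_o − E_a·E_o)), with monotherapy
inhibitions taken from the zero-dose row and column of the same surface.
The score is computed in survival space as 100 × (s_a·s_o − s_obs), which
is algebraically identical but makes surfaces with exactly multiplicative
survival score exactly zero in floating point. Survival values outside
[0, 1] (relative outgrowth) are clipped for the Bliss formula only, with a
warning; raw values are preserved everywhere else. Monotherapy cells do
not enter the averaged score.

One caveat worth stating explicitly: the synthetic growth model applies
drug action multiplicatively to the growth *rate* (below), so the measured
4-day relative survival is exp(g(s_a·s_o − 1)t), which is not the product
of the measured monotherapy survivals. Panels simulated without any
interaction term therefore show a small negative mean score (≈ −2 to −3
points) — mild apparent antagonism that is a property of exponential
growth kinetics, not of the scoring. The detection-power test instead
verifies that an injected interaction term shifts scores positive relative
to that baseline, and the exact-zero property is verified on surfaces that
are multiplicative in measured space.

Four-parameter logistic fits (response = bottom + (top−bottom)/(1 +
(dose/IC50)^hill)) use deterministic multi-start least squares with IC50
seeds log-spaced from a tenth of the lowest to ten times the highest
tested dose; the lowest-RSS start wins, fits whose IC50 leaves the tested
range are flagged, and total non-convergence returns a flagged fit with
infinite RSS.

## In vivo clonal dynamics

Tumor volume uses the caliper formula π/6 × large × small²; swapped
diameters are exchanged with a warning. Regimens are day-indexed schedules
built from shorthand codes (A/O/G monotherapy, A+O and G+O simultaneous,
AO/GO/OA/OG sequential with a switch day, AO3 three-day alternation,
vehicle), validated contiguous and non-overlapping, with an untreated
engraftment window before the start day.

Intratumoral composition comes from barcode counts of resected-tumor DNA:
per-tumor variant proportions (summing to 1) and abundances scaled to the
GFP reference clone, averaged arithmetically across the mice killed at a
(group, day); a geometric-mean option exists for heavily skewed
compositions. Per-variant drug sensitivity in vivo is the relative tumor
volume: RTV_v = (mean proportion_v × mean volume)_treated /
(mean proportion_v × mean volume)_vehicle at a fixed day (default 15).
The proportion × total-volume decomposition makes the abundance-weighted
mean RTV reproduce the total-volume ratio exactly (tested); proportion
alone is recoverable by passing equal volumes. Variants below a
configurable vehicle-proportion floor are flagged undefined — rare clones
are drained from a competitive pool and their ratios are unstable.
Group comparisons use the two-sided paired t test; zero variance of the
paired differences is flagged degenerate rather than given a p value.

## The synthetic-data generator

The generator provides ground truth for every stage. Its model:

- **Clones.** Each clone has 1–3 unique random 10-mer barcodes, a drug-free
  log growth rate g (per day), and per-drug Hill inhibition
  I(c) = Imax/(1 + (IC50/c)^h). Growth rates are drawn around 0.7/day
  (roughly one doubling per day in suspension culture, σ = 0.05);
  dual-resistant clones draw around 0.85/day, mirroring the strong
  proliferative advantage of exon-20-insertion variants in competition.
- **Archetypes.** Four sensitivity classes emulate the screen's observed
  pattern space: sensitive to both drugs (afatinib IC50 ≈ 2 nM,
  osimertinib ≈ 20 nM, Hill 2, Imax 1, with 20% lognormal jitter);
  resistant to both, to afatinib only, or to osimertinib only (resistance
  modelled as Imax = 0.1, i.e. ≥ 90% of growth retained at any dose).
  Gefitinib sensitivity tracks afatinib (first/second-generation TKIs
  share their target spectrum). The default archetype mix
  (0.82/0.09/0.01/0.08) approximates the screened panel's composition.
  Reference clones are drug-inert; KRAS G12V grows near the pool average,
  while the GFP clone is non-transforming and nearly static (0.1/day) —
  otherwise a drug-inert fast grower would overrun every treated tumor.
- **Growth under drug (in vitro).** N_v(t) = N_v(0)·exp(g_v·s_v(c)·t) over
  t = 4 days, with the survival factor s_v(c) the product of per-drug
  (1 − I_d) terms; an optional interaction term ε multiplies in (1 − ε)
  whenever two or more drugs are present, so ε = 0 is exact independence
  at the rate level. The quantity the analysis estimates is the relative
  survival exp(g(s − 1)t), emitted as the truth table.
- **Sequencing.** Reads per sample are multinomial at the configured depth
  from Dirichlet-perturbed clone proportions. The in vitro concentration
  default (2000) yields replicate CVs of ~10–15%, typical of pooled
  amplicon screens; tumor samples default to 200 because manual
  subdivision and dissociation of tumors is a much noisier sampling step.
  Overdispersion can be disabled for closed-form comparisons.
- **Tumors.** Per-mouse clone masses follow day-by-day dynamics with net
  rate (g_invivo + δ)·s − δ, where g_invivo = 0.4·g (xenografts grow
  slower than suspension culture; the scale makes a ~1.5 mm³ graft reach
  ~100 mm³ of vehicle tumor by day 15) and δ = 0.3/day is baseline
  turnover, so a fully inhibited clone regresses rather than merely
  stalling. The turnover term leaves the in vitro analysis untouched
  (δ cancels in any treated/vehicle ratio) but is what lets sequential
  regimens differ: without regression, a clone's gain from its permissive
  phase would persist regardless of drug order. Drug exposure in vivo uses
  fixed effective concentrations (afatinib and gefitinib 10 nM,
  osimertinib 100 nM). Total mass maps to volume, split into large/small
  caliper diameters via a lognormal eccentricity (σ = 0.1, large ≥ small)
  with 5% lognormal measurement noise; barcode counts at kill days are
  Dirichlet-multinomial draws from the clone masses.
- **Reads.** FASTQ emission plants each barcode's cassette at a random
  offset in random background sequence, applies substitution errors at a
  configurable rate, and writes mate 2 as the reverse complement of the
  mate-1 template with independent errors. Fixed seeds give byte-identical
  files.

The regimen-comparison scenario (`make_regimen_panel`) places one dominant
afatinib-resistant/osimertinib-sensitive clone in a background of
drug-sensitive clones plus rare pre-existing dual-resistant subclones at
10⁻⁴ initial frequency — the realistic pre-treatment range for resistant
subclones; at percent-level frequencies their unchecked growth dominates
every arm and erases the switching-order contrast. The schedule used in
tests and the acceptance script is a compressed 15-day course with the
switch at day 6, preserving the longer-second-phase structure of the
30-day animal schedule it emulates. Under these conditions simultaneous
combination beats afatinib-then-osimertinib beats the reverse order
(the dominant clone expands during whichever phase contains afatinib and
regresses under osimertinib; a longer closing osimertinib phase removes
more of it).

### What the generator does and does not emulate

It reproduces the statistical structure the analysis relies on: equal
initial mixing, exponential competition, Hill-type dose response,
reference-scaled depth cancellation, multinomial sequencing with
overdispersion, and read-level cassette structure with substitution
errors. It does not model PCR chimeras or indels, Illumina quality
profiles, clonal evolution (new mutations under treatment), carrying
capacity or spatial structure in tumors, or drug pharmacokinetics. Passing
tests therefore demonstrate that the pipeline recovers what these
experiments measure under their stated noise model, not that any
particular biological variant behaves as simulated — simulator parameters
are archetype-based synthetic values, not estimates for real variants.

## Numerical choices and degenerate inputs

- Pseudocount 0.5 on all counts before reference scaling; reference rows
  are exactly 1; samples with a zero reference count are flagged.
- Dose matching on surfaces uses relative closeness (rtol 1e-9, atol 0) —
  molar doses span picomolar to micromolar, so any absolute tolerance
  would conflate nanomolar levels with the zero dose.
- Empty FASTQ files yield an all-zero column with a warning, not an error;
  desynchronised read pairs and malformed records raise with the record
  index.
- Variants with zero vehicle signal, absent day-0 counts, undetermined
  calls, or missing vehicle proportions are flagged/excluded and reported,
  never silently dropped.
- Problem sizes in the test suite and acceptance script (24–60-variant
  panels, 10⁵-read round trips, depth-10⁶ screens, 10-seed regimen
  comparisons) were chosen as the smallest sizes at which the statistical
  claims are comfortably resolved.

## Known limitations

- The three-way sensitivity cutoffs (0.2/0.5 survival at top dose) are a
  deterministic convention, not a calibrated decision rule.
- The RTV definition (proportion × total volume) is the most direct
  reading of a per-variant "relative tumor volume"; proportion-only RTV is
  computable but not the default.
- Bliss scoring is the only synergy model implemented (no Loewe/HSA/ZIP),
  and no significance test accompanies the scores.
- The barcode counter does no error correction toward the map; with dense
  barcode spaces (pairwise Hamming distance 1) a sequencing error could
  silently reassign a read — the panel generator keeps barcodes unique but
  does not enforce a minimum pairwise distance.
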