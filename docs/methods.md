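# Methods

`faerspv` implements the standard analysis chain for drug-safety signal
detection on FAERS-format spontaneous adverse-event reports, applied here
to drug-induced acute respiratory distress syndrome (ARDS, MedDRA
preferred term 10001052). This note records the models, the defaults and
why, the numerical choices, and what the synthetic study design does and
does not establish.

## Case cleaning

FAERS quarters arrive as "$"-delimited ASCII tables (DEMO, DRUG, REAC,
OUTC, THER) keyed by PRIMARYID, where one patient case (CASEID) may
appear as several report versions. Cleaning follows the FDA-recommended
convention:

1. **Deduplication.** Among all versions of a CASEID, keep the one with
   the most recent FDA_DT; on exact FDA_DT ties, keep the numerically
   highest PRIMARYID. A version with an unparseable FDA_DT sorts as
   minimal and can never displace a dated one. The rule is a pure
   maximum over a totally ordered key, so it is idempotent and invariant
   to input order — both are tested properties.
2. **Deletion lists.** Quarterly deletion-report lists (published since
   2019Q1) remove cases by CASEID after deduplication. Listed CASEIDs
   absent from the corpus are ignored and logged.
3. **Flow accounting.** `raw − duplicates − deleted = unique` is asserted
   on every run, and on synthetic data the removed-duplicate count must
   equal the planted count exactly.

Dates are held at their reported precision (`YYYYMMDD`, `YYYYMM`,
`YYYY`); only full-precision dates enter day arithmetic. This is the
conservative choice: coercing `202001` to January 1st would manufacture
onset intervals that were never reported.

Dictionary standardization is a pluggable table lookup (TSV files mapping
PT code → PT name/SOC and normalized verbatim drug name → ingredient),
standing in for the licensed MedDRA and WHO Drug dictionaries, whose
content cannot be redistributed. Verbatim names are uppercased, stripped
of punctuation and whitespace-collapsed before lookup; unmapped names
pass through tagged and are reported with frequencies. Within a case the
same standardized ingredient is merged (roles unioned, earliest
full-precision therapy start kept) so a combination product or repeated
course never counts twice in a contingency table.

Age normalization: DEC ×10, YR ×1, MON ÷12, WK ÷52.1775, DY ÷365.25,
HR ÷8766, producing years; a value with a missing unit is assumed YR and
flagged; results above 120 years are set missing as implausible.
Reporter occupation codes map to the six standard categories (Physician,
Pharmacist, Other health-professional, Consumer, Lawyer, Not Specified).

## Disproportionality statistics

The counting unit is the deduplicated case, so for each drug
N = a+b+c+d equals the corpus (or stratum) size. All four estimators are
implemented exactly as conventionally defined on the 2×2 table:

| statistic | definition | signal criterion |
|---|---|---|
| ROR | ad/(bc), SE(ln ROR) = √(1/a+1/b+1/c+1/d) | a ≥ 3 and CI₉₅ lower > 1 |
| PRR | (a/(a+b))/(c/(c+d)), SE(ln PRR) = √(1/a−1/(a+b)+1/c−1/(c+d)) | a ≥ 3, PRR ≥ 2, χ² ≥ 4 |
| χ² | N(ad−bc)²/((a+b)(a+c)(c+d)(b+d)), no continuity correction | — |
| IC | log₂((a+0.5)/(E+0.5)), E = (a+b)(a+c)/N | IC025 > 0 |
| EBGM | aN/((a+c)(a+b)), log-normal Wald CI | EBGM05 > 2 |

The IC credible bounds use the closed-form approximations
IC025 = IC − 3.3(a+0.5)^−1/2 − 2(a+0.5)^−3/2 and
IC975 = IC + 2.4(a+0.5)^−1/2 − 0.5(a+0.5)^−3/2. The full BCPNN
posterior quantities E(IC), V(IC) and IC−2SD are also computed from the
Dirichlet prior with counts α₁ = β₁ = γ₁₁ = 1, α = β = 2; the default
BCPNN signal criterion is IC025 > 0, with IC−2SD > 0 available as a
variant (`bcpnn_criterion="ic_minus_2sd"`) since both appear in the
pharmacovigilance literature. An unsmoothed IC point estimate
log₂(a/E) is exposed (`ic_smoothed=False`) because published tables are
sometimes computed that way; the credible bounds always use the
smoothed form.

**EBGM caveat.** The EBGM implemented here is the crude relative
reporting ratio with a Wald interval — the definition used in the study
this package reproduces — not DuMouchel's gamma-Poisson shrinkage
estimator. For a ≥ 3 and the large margins typical of FAERS the two are
close, but the crude form does not shrink sparse cells. "EBGM05" is the
z = 1.96 lower bound of the log-normal interval, not a posterior 5th
percentile, despite the conventional name.

**Zero cells.** A zero in any cell triggers a Haldane–Anscombe +0.5
correction on all four cells, with the estimate flagged `corrected`.
Published FAERS tables never confront this (all reported a ≥ 3), so the
choice is ours; +0.5-everywhere keeps ROR defined and symmetric.

**Stratification.** Tables are rebuilt within each level of sex, age
band, or reporter category, with N equal to the stratum size; every
statistic is recomputed from the stratum table. Output is ranked by a
descending, ties broken by drug name, so output ordering is
deterministic.

**Known published-value discrepancies.** Back-solving full tables from
published marginals (a, a+c, N, EBGM) reproduces published PRR, χ² and
EBGM05 at printed precision, but published ROR values run ≈0.4% below
the ROR of those same cells, and published IC values match log₂(EBGM)
rather than the 0.5-smoothed form. The source's exact denominator
conventions for those two columns are not stated; both variants are
exposed, and ROR/IC are deliberately not used as reproduction checks.

## Time-to-onset

TTO = event date − earliest full-precision therapy start of the drug, in
whole days; day 0 (same-day onset) is valid. Negative intervals — which
occur in real reports — and pairs with missing or partial dates are
excluded from statistics and fits but reported as their own segment.
Case-level segmentation uses inclusive integer bins (0–30, 31–60, …,
181–360, >360 days) matching the contiguous printed labels; when a case
lists several drugs its smallest valid per-drug interval is used.
Quartiles use linear interpolation between order statistics; SD uses the
n−1 denominator.

Per-drug onset samples with n ≥ 3 valid values are fitted with a
two-parameter Weibull by maximum likelihood (scipy's MLE refined by a
Nelder-Mead polish on (log α, log β)). Zero-day onsets are replaced by
0.5 day *for fitting only* (the Weibull support is positive); the
descriptive statistics keep 0. 95% CIs are Wald intervals on the log
parameters from a finite-difference observed information matrix,
back-transformed — standard for Weibull MLE and consistent with the
asymmetric CIs seen in published onset tables. The shape CI classifies
the hazard: entirely below 1 → early failure, containing 1 → random,
entirely above 1 → wearout. Samples with zero variance (all-identical
onsets) or a non-invertible information matrix are flagged *degenerate*
rather than reported with an arbitrary capped shape, as some software
prints (e.g. a 3998.69 cap); the published cap artifact is deliberately
not reproduced.

Parameter recovery is verified by simulation: at n = 100 (scale 50,
shape 0.7) over 200 replicates the median relative bias of both
estimates is below 5% and shape-CI coverage is ≥ 90%; at n = 500 both
parameters are recovered within 10%. The likelihood maximum is pinned by
an independent coarse-to-fine grid search and cross-checked against
lifelines' independent Weibull MLE.

## Synthetic study design

The generator emits the exact file dialect the reader consumes, plus a
ground-truth manifest. Defaults are the study conditions: 50,000 cases,
baseline target-event probability 0.005, one drug planted at relative
rate 10 (exposure 2%) over twenty background drugs at RR 1 (exposure 5%
each). Under polypharmacy the event probability is
`baseline × max(RR of exposed drugs)` — the max rule, not multiplicative
— so each drug's marginal RR stays interpretable and expected tables can
be computed in closed form for tests. Where no study value exists the
defaults are chosen once as realistic for spontaneous-report data: 5%
duplicate-version rate, 0.5% deletion-list fraction, 60% of cases losing
a date plus 5% with reversed date order (≈65% missing/abnormal onset
block, close to the ≈70% typical of real onset data). Demographic
category distributions default to those of a large drug-induced ARDS
case series (46.69% male, 42.81% female; 26.01% aged ≥65; physician
reporters 40.54%; hospitalization 65.04%, death 51.21% as non-exclusive
outcomes), so descriptive output resembles real profiles. Onset
intervals for event cases follow the causing drug's Weibull (default
scale 50 d, shape 0.7 — an early-failure pattern). All randomness flows
from one mandatory seed; the same config yields byte-identical files.

What the synthetic design does **not** emulate: correlated
co-prescription, calendar-time reporting trends, event-dependent
reporting delay, duplicate versions that differ in content, and
free-text noise in drug verbatims beyond suffix variants. Passing
recovery tests therefore shows the pipeline is correct and well-calibrated
under independence, not that real-world confounding (channeling,
stimulated reporting, masking by other signals) is handled — no
disproportionality method handles those.

## Problem sizes and determinism

The test suite and the analysis scripts use a 50,000-case corpus
(~300 target cases), chosen so that binomial sampling error keeps the
planted-RR recovery band tight while the full suite runs in minutes on
one CPU; estimator unit tests run on fixed tables and complete in
milliseconds. The consistency checks against published statistics are
exact arithmetic on reconstructed 2×2 tables and involve no sampling.
Pipeline reruns on identical inputs produce byte-identical artifacts;
the written run log is sequence-numbered rather than wall-clock-stamped
for this reason.

## Known limitations

- The crude EBGM (no shrinkage) overstates sparse-cell signals relative
  to true MGPS; the a ≥ 3 gate mitigates but does not remove this.
- Exposure counting includes all role codes (PS/SS/C/I) by default;
  restricting to suspect drugs (`roles={"PS","SS"}`) is supported and
  changes counts materially in real data.
- The choice of event_dt (rather than reaction report date) and of the
  earliest therapy start for multi-course therapy is a convention;
  published onset analyses rarely state theirs.
- No multiple-testing correction beyond the conventional conjunctive
  thresholds is applied.
- Pre-2012 LAERS column dialects and XML dumps are out of scope.
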