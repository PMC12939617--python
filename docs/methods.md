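# Methods

This note documents the statistical procedures, the synthetic-data design,
the numerical choices, and the known limitations of the package. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model and preprocessing

The unit of analysis is one deduplicated safety report. Quarterly tables
(DEMO, DRUG, REAC, THER, OUTC, INDI, RPSR) are `$`-delimited ASCII with one
header row, joined on PRIMARYID; rows whose PRIMARYID never appears in DEMO
are orphans, excluded and counted. The dialect has no quoting, so a literal
`$` inside a value is unrepresentable and raises on write. Headers are
case-insensitive; unknown columns are preserved but ignored; undecodable
bytes are replaced and logged.

**Deduplication.** Reports arrive as CASEID-versioned updates. Per CASEID
the retained version is the one with the latest FDA_DT, ties broken by the
largest PRIMARYID. CASEID compares as a string; FDA_DT and PRIMARYID
compare numerically, non-numeric PRIMARYIDs falling back to lexicographic
order after all numeric ones (the retention rule names the fields but not
the comparison type; numeric comparison matches how these identifiers are
assigned). The operation is idempotent and invariant under input
permutation because the sort key is total.

**Age.** AGE/AGE_COD pairs convert to years: YR×1, MON÷12, WK÷52, DY÷365,
DEC×10. Negative values, unknown codes (including HR) and missing entries
map to missing. The pediatric filter retains 0 < age < 18 strictly on both
ends; missing ages are excluded, never imputed.

**Primary Suspect.** Drug-level exposure is the report's PS-role drug with
the lowest DRUG_SEQ; non-numeric sequence values order after every numeric
one. Reports without a PS row are excluded from drug-level analysis but
remain in the background population (a configuration switch,
`background="ps_assigned"`, restricts the margins instead; the default
keeps the full deduplicated pediatric background).

**Time to onset.** EVENT_DT − START_DT in days. Every report receives
exactly one category: `missing` (either date absent), `incomplete` (fewer
than eight digits, or not a valid calendar date), `inconsistent`
(difference ≤ 0), `implausible` (difference > 6,574 days = 18 years, a
bound chosen to be inert for pediatric subjects; configurable), else `ok`
with the day count. Partial dates are never imputed.

## Case definition and drug names

Cases are reports carrying any of six cataract Preferred Terms
(10069649 Atopic cataract, 10007739 Cataract, 10007748 Cataract cortical,
10007759 Cataract nuclear, 10044135 Toxic cataract, 10024214 Lenticular
opacities); the narrow sensitivity mode uses 10007739 alone, so narrow
cases are a subset of broad cases by construction. The full MedDRA
hierarchy is licensed and not shipped; `PtQuerySet.from_json` accepts a
user-supplied set.

Drug-name harmonisation is a plain TSV (verbatim → generic entity,
combination flag, pharmacological class) with case-, whitespace- and
punctuation-insensitive lookup. Salts and esters consolidate to the base
ingredient except where an explicit entry keeps an ester distinct
(prednisolone acetate, an ophthalmic product with its own risk profile,
stays separate from prednisolone). Combination products are entities of
their own, never folded into components. Unmapped names pass through as
normalised verbatim, flagged and counted, so screening still covers them.
The packaged table covers the 24 signal drugs of the pediatric-cataract
analysis plus common brand/salt variants; it is deliberately editable data,
not code.

## Disproportionality statistics

All four statistics derive from the per-drug 2×2 table (a, b, c, d) against
the deduplicated pediatric background, N = a+b+c+d.

- **ROR** ad/bc with Wald CI exp(ln ROR ± 1.96·SE), SE = √(1/a+1/b+1/c+1/d);
  flag: a ≥ 3 and CI lower > 1.
- **PRR** [a/(a+b)]/[c/(c+d)], CI with SE = √(1/a − 1/(a+b) + 1/c − 1/(c+d));
  χ² is the Yates-corrected statistic N(|ad−bc|−N/2)²/[(a+b)(c+d)(a+c)(b+d)],
  clamped to 0 when N/2 ≥ |ad−bc|; flag: a ≥ 3 and χ² > 4 (strict).
- **BCPNN** raw IC = log₂[aN/((a+b)(a+c))]; posterior moments E(IC), V(IC)
  under Dirichlet-style priors α₁=β₁=1, α=β=2, γ₁₁=1 with the per-table
  normaliser γ = γ₁₁(N+α)(N+β)/[(a+b+α₁)(a+c+β₁)]; IC−2SD = E(IC) − 2√V(IC).
  The flag is E(IC) > 0; because figure conventions elsewhere often flag on
  the IC025-style bound instead, a strict mode (`bcpnn_strict`) flags on
  IC−2SD > 0. Both quantities are always reported.
- **EBGM** here is the *unshrunk relative reporting ratio* aN/[(a+b)(a+c)]
  with EBGM05 = exp(ln EBGM − 1.95·SE), SE as for ROR, and flag a > 0 and
  EBGM05 > 2 — implemented exactly as used in the pediatric-cataract
  analysis, including the 1.95 multiplier. This is **not** DuMouchel's
  gamma-mixture MGPS: no empirical-Bayes shrinkage is applied, so small-a
  estimates are more dispersed than true EBGM scores. Users wanting real
  MGPS shrinkage should treat this column as O/E.

Zero cells make ROR/PRR/EBGM05 undefined; no Haldane 0.5 continuity
correction is applied anywhere (none is part of the flagging conventions
implemented here), and undefined statistics count as *not flagged*. The
consensus signal is the conjunction of all four flags — deliberately
conservative; the test suite measures its false-positive rate under a null
world at well below 1%.

Screens report every drug with a ≥ 3 (configurable), sorted by descending
ROR, ties broken by larger a then lexicographic name. Wald intervals are
symmetric on the log scale, so the geometric mean of the CI bounds equals
the point estimate; `point_from_wald_ci` exposes this bridge, which the
acceptance script uses to reconstruct published point estimates from their
printed bounds to within printed precision.

## Time-to-onset model

Usable onsets (category `ok`) are uncensored positive day counts. The
Weibull fit is maximum likelihood in (log shape, log scale) via Nelder–Mead
on the analytic log-likelihood, with 95% Wald CIs from the observed
information (numerical Hessian on the log-parameter scale, then inverted).
Log-scale CIs keep both parameters positive and are close to
profile-likelihood intervals at these sample sizes. Fits are refused below
n = 10 or for degenerate all-equal samples. Point estimates agree with an
independent Weibull MLE (lifelines) to four significant figures in the test
suite; shape 0.72 at n = 5,000 is recovered within ±0.03 and CI coverage is
at nominal level within Monte-Carlo tolerance.

Histogram bins are left-open/right-closed — (0,30], (30,60], (60,90],
(90,180], (180,360], (360,∞) by default — so day 30 falls in the first bin;
only the >360-day category is anchored by published numbers, and all edges
are configurable. The two-group onset comparison (glucocorticoid vs other,
classes from the drug-name table) uses product-limit curves and the
two-sample log-rank test via lifelines; since spontaneous reports contain
only observed events, the curves are empirical survival complements with no
censoring model. An interval-censoring or detection-lag adjustment is
deliberately out of scope: the reported onset is report-interval, not
biological onset.

One published inconsistency is not reproduced: a quoted 17.51% share for
0–30-day onsets is incompatible with the stated n = 127 (22/127 = 17.3%,
23/127 = 18.1%); the package computes bin percentages only from actual
counts.

## Synthetic world

The generator emits a complete quarter bundle plus a latent ground-truth
record per report. Design points that matter for validity:

- **Planted associations** act only through the Primary-Suspect drug: a
  report's cataract probability is ρ·(background probability) for its PS
  drug, so for rare events the realised ROR concentrates near ρ. An
  optional per-pair PT subset restricts which cataract PTs planted cases
  carry (used to construct narrow-PT scenarios). Configurations with
  ρ×background > 1 are rejected.
- **Duplicates** are extra CASEID versions with earlier FDA_DT or — with
  configurable probability — identical FDA_DT and a smaller PRIMARYID, so
  both branches of the retention rule are exercised; the base version is
  always the one the rule must keep, and carries the same content, so
  ground truth is version-invariant.
- **Ages** are drawn in years and emitted in a mixed unit (YR/MON/WK/DY/DEC)
  with four-decimal formatting; the latent truth is recomputed *from the
  emitted string*, so pipeline-vs-truth comparisons are exact and free of
  round-trip artefacts. Pediatric draws live in (0.25, 17.75) years and
  adult draws in (18.5, 85), keeping every value away from the 0/18
  boundaries where a last-ulp difference could flip the filter.
- **Dates** follow a Weibull(shape, scale) onset model; each report gets
  exactly one injected pathology category (ok / missing / incomplete /
  inconsistent / implausible) with configured probabilities, and valid
  onsets are clipped to [1, 6574] days so injected categories equal the
  pipeline's categorisation exactly (an unclipped Weibull(0.72, 300) tail
  would cross the implausibility bound with probability ≈ 1e-4).
- **Determinism**: one `numpy` Generator seeded from the config; identical
  (config, seed) produces byte-identical files.

The `paper_like_config` preset is a pediatric-only world of 24 planted
signal drugs (classes included: 11 glucocorticoids, monoclonal antibodies,
immunosuppressants, three CFTR modulators, antineoplastics, an
antiepileptic, a colony-stimulating factor) over a 0.1% background cataract
rate, onset Weibull(0.72, 300 d), and 70%/10%/2% missing/incomplete/
inconsistent dates — the reporting conditions of the pediatric-cataract
study, scaled to a 50,000-report world that generates and screens in
seconds. Exposure probabilities and rate ratios are fixed demo conditions
chosen once: rare ophthalmic products carry extreme ratios (difluprednate
ρ = 500), systemic drugs common exposure and moderate ratios (5–30).

What the generator does **not** emulate — and hence what passing tests do
not show about real FAERS data: real drug co-prescription and
confounding-by-indication structure (each report has one independent PS
draw), schema drift across 83 quarters, true verbatim-name noise beyond
case/spacing, reporting-rate secular trends, and the indication-driven
clustering that makes real disproportionality signals confounded. Tests
demonstrate *algorithmic correctness against known truth*, not clinical
validity of any signal.

## Problem sizes and tolerances

The default suite uses 50,000-report worlds for exact oracle equivalence
and planted-signal recovery (20 seeds), a 100,000-report world with 1,000
null drugs for the consensus false-positive rate, 100 replicates for CI
coverage, and 10,000 random tables for the χ² oracle comparison — sizes at
which every binomial/Monte-Carlo tolerance asserted in the tests has
comfortable slack, while the whole suite runs in a couple of minutes on one
CPU. Numerical agreement thresholds: 1e-10 (relative) against independently
coded closed-form oracles; 1e-4 against the independent Weibull MLE.

## Known limitations

- EBGM is the unshrunk O/E ratio (see above), by design.
- The Wald CIs for ROR/PRR are asymptotic; with a ≤ 3 their coverage is
  approximate, which is precisely why the a ≥ 3 gate exists.
- The drug-name table is a curated seed, not a full RxNorm/ATC mapping;
  real-data use requires extending the TSV.
- No stratified or age-adjusted disproportionality, and no
  indication-based background restriction — matching the analysis the
  package implements, which performed none.
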