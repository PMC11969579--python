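# Methods

## Model structure

The package couples two components evaluated in annual cycles from the cohort
start age (40 or 50) to a configurable maximum age (default 100, after which
death is absorbing):

1. **Screening cascade (decision tree).** In each cycle in which screening is
   due (every cycle, or cycles 0, 5, 10, … for quinquennial strategies, while
   the cohort is ≤75), a fraction `coverage` of the eligible population is
   screened. Per true health state the tree yields the probability of being
   flagged, referred, confirmed and started on treatment, and the expected
   programme/work-up cost per person entering the cycle. Confirmatory
   diagnosis at higher facilities uses gold-standard tests assumed to reveal
   the true state: truly diseased attendees are confirmed, false positives
   are cleared, pay the work-up cost, and return to the undiagnosed pool in
   the same cycle.
2. **Natural history (Markov cohort model).** Two mutually exclusive,
   forward-only disease arms under the ISGEO staging: OHT → mild → moderate →
   severe → unilateral → bilateral blindness (open-angle) and PACS → PAC →
   PACG → unilateral → bilateral blindness (angle closure). Each living
   diseased stage carries care flags (undiagnosed / diagnosed-untreated /
   treated); flags triple the diseased states, giving 35 states in total.
   Treatment multiplies the stage-progression probability by an arm-specific
   relative risk and never changes the utility of a given vision state.

Within a cycle the order is: organised screening (if due) → opportunistic
usual-care detection → valuation of state membership (no half-cycle
correction; membership valued at cycle start) → transition. Both detection
pathways operate in every arm and are independent; usual care simply has no
organised component.

### Competing risks and incidence

Death is resolved first: at age *a* the background probability q(a) comes from
the life table (multiplied by the blindness multiplier, default 2.34 for both
unilateral and bilateral blindness, capped at 1), and progression/incidence
apply to survivors, so a forward move has probability (1−q)·p. Rows of the
transition matrix therefore sum to 1 by construction and are never
renormalised. Because of the death-first convention, one-cycle disease
incidence is reported per person **alive at the end of the cycle** — new
entries divided by surviving mass — which recovers the configured annual
incidence rates (370/489/530 per 100,000 for OHT/POAG/PACS) exactly, matching
how incidence rates are defined in the cohort studies they come from.

### Screening channels

Each true state is screened through its designated channel: tonometry for
raised pressure (OHT, and a second chance for POAG), fundus imaging for POAG
structural damage (human grading in F2F mode, algorithmic grading in AI mode,
each with its own sensitivity/specificity and an extra per-scan cost), and
tonometry followed by the oblique flashlight test *in series* (positive only
if both positive: sens = s₁·s₂, spec = sp₁ + (1−sp₁)·sp₂) for angle closure.
A fixed fraction of fundus images (default 22%) is ungradable and routed
straight to referral regardless of the true state. A person is referred if
any channel flags them; cross-channel false positives (e.g. an OHT patient
flagged by a fundus false positive) are allowed, because the referral reason
is irrelevant once the gold standard examines the patient. A consequence
worth knowing: "zero sensitivity" alone does not make a screening arm inert —
diseased people can still reach confirmation through fundus false positives
or ungradable images. The genuinely inert configuration is sens = 0,
spec = 1, ungradable = 0, and that is what the equivalence tests use.

### High-risk strategies

High-risk strategies screen only the high-risk subgroup (diabetes,
hypertension or family history; default 35% of the population with disease
relative risk 2.0). The cohort is not stratified by risk; instead screening
reach is computed in expectation: a disease-free person is screened with
probability coverage·f, a diseased person with probability
coverage·f·rr/(f·rr + 1 − f) — the enrichment of diseased persons inside the
high-risk subgroup under conserved population totals.

### Usual-care detection

The 10% annual consultation probability applies, as a per-cycle hazard, to
undiagnosed *manifest* glaucoma (mild+ POAG, PACG and blind states);
asymptomatic precursors (OHT, PACS, PAC) are not detected opportunistically.
80% of confirmed consulters initiate treatment. Diagnosed-but-untreated
persons (lost between confirmation and treatment) are assumed to remain
untreated.

## Costs and utilities

All costs are in 2022 Indian rupees with no internal inflation adjustment.
Annual treatment costs (consultations, diagnostics, medicines, non-medical
travel) accrue to treated states only; undiagnosed and diagnosed-untreated
states accrue nothing. Costs are sector-weighted: public share of outpatient
contacts (default 37.8%) for consultations/diagnostics/medicines, public
inpatient share (default 32%) for surgery. Medicines at public facilities are
free only up to the availability fraction (default 20%); the shortfall, and
all private-sector care, is out-of-pocket. Surgery is a one-time cost at
treatment initiation: laser iridotomy for any angle-closure stage,
trabeculectomy for severe+ open-angle disease; medication costs continue
after surgery. Screening programme cost per screened person is the variable
per-screen cost (+ per-scan fee in AI mode) plus per-PHC overheads
apportioned over the persons screened in one round (overheads accrue over
the full five years between quinquennial rounds). Indirect/productivity
costs are out of scope.

Utilities are EQ-5D-5L-style values per vision state, multiplied by a
population-average comorbidity utility (share-weighted over none /
hypertension / diabetes / both). Dead is 0; treatment does not change the
utility of a vision state.

## Economics

Discounting at 3%/year, df(t) = (1+r)⁻ᵗ, cycle 0 undiscounted. ICURs are
computed from full-precision internals; display rounding happens only in
reports. Dominance: cheaper-and-at-least-as-effective is *dominant* (cost-
effective at any threshold); costlier-and-no-better is *dominated*; a zero
QALY difference yields a label, never a ratio. PSA holds demographics, the
discount rate and the threshold fixed, draws every parameter with a positive
standard error from its moment-matched beta/gamma distribution (uncorrelated
draws), and runs all strategies plus comparators on the same draw; a fixed
seed is bit-reproducible. Scenario grids override the public shares (both
set to the grid value) and medicine availability for the *screened pathway's*
post-referral care only; the usual-care comparator keeps baseline behaviour.
Loss-to-follow-up rates are varied in PSA but never in scenario analysis.

## Synthetic inputs and what tests do and do not show

The published evaluation keeps most quantitative inputs in an untranscribed
supplementary file. The packaged defaults therefore mix exact main-text
anchors with a synthetic placeholder block, flagged in each parameter's
`provenance` field and chosen once to be plausible for screening-age Indian
adults: glaucoma-spectrum baseline prevalence ≈6.5%, annual stage-progression
probabilities 4–8%, treatment relative risks 0.5 (medical, open-angle) and
0.4 (iridotomy, angle closure), public:private cost ratios of roughly 1:3–4,
and utilities declining from 0.92 (disease-free) to 0.45 (bilateral
blindness). Standard errors are synthetic: 10% of the value (3% for
utilities, capped to keep beta moments feasible). The life table is a
synthetic Gompertz schedule (q₄₀ = 0.0025 rising at 0.085/year to age 100)
standing in for national Sample Registration System tables, and is shipped as
a fixed fixture, not sampled.

Consequently the package reproduces the published model's *structure and
mechanisms* — the direction and rough magnitude of QALY gains, the
not-cost-effective base case, the ICUR decline under public-sector
strengthening, the OOPE mechanism — but its headline rupee values are not
expected to equal the published ones, and tests assert published numbers only
where they are recomputable from printed values or are stated model inputs.
Real supplementary values can be dropped in via a YAML override file without
code changes.

## Numerical choices

- Cycle counts: ages start…max inclusive; LY accrues for the cycle in which a
  person is alive at cycle start (so q = 1 still accrues the first cycle).
- Conservation is structural; traces are asserted to sum to 1 within 1e-9.
- Beta moment matching requires se² < m(1−m); infeasible requests fail fast
  at distribution construction.
- Deterministic-sensitivity ranges default to ±10% (±50% for costs), clipped
  to [0,1] for probabilities and utilities; explicit low/high win.
- Problem sizes in the test suite: property checks run 50 randomised
  parameter sets through full lifetime runs; PSA-based tests use 25
  iterations on a horizon shortened to age 70; the decision-tree Monte Carlo
  oracle simulates 200,000 paths. These sizes give comfortable statistical
  margins (4 Monte-Carlo standard errors) at interactive runtimes.

## Known limitations

- Cohort expectations only: no individual-level microsimulation, so
  screening-history correlation (e.g. repeated non-attenders) is not
  representable.
- No dual-disease states (POAG and PACD are mutually exclusive arms), no
  disease regression, no treatment disutility or adverse events.
- The high-risk enrichment is an expectation-level approximation rather than
  an explicit risk-stratified cohort.
- Diagnosed-but-untreated persons never re-enter care.
- Uncorrelated PSA draws; no EVPI; no budget-impact scaling.
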