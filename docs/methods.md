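# Methods

## The validation design

Two surveillance systems observe overlapping sets of people. The
*passive* system is administrative: insurance (Medicaid and private)
claims and hospital discharge records, 1998–2012, carrying ICD-9-CM
diagnosis codes, service dates, care setting, provider specialty, and
prescriptions. The *active* system is a nurse review of specialty-practice
medical records that labels each reviewed person a confirmed case (with
subtype) or not. Linking the two on an exact person key partitions the
union into both / passive-only / active-only; algorithm validation happens
on the linked ("both") persons, because only they have both the claims
predictors and a gold-standard label.

A *case-definition algorithm* is a conjunction of per-person predicates
derived from claims. Its quality is summarized by the accuracy statistic,
the positive predictive value TP/(TP+FP) among flagged linked persons.
Sensitivity within the linked universe is also available, but PPV is the
headline number: for rare diseases the cost of passive surveillance is
false positives.

## Predictor derivation

Each person's claim history is collapsed into one feature row per
derivation code set (any-MD, or a single MD code):

- **code count** — the number of *distinct service dates* bearing a
  target code. Distinct dates, not claim lines, so same-day duplicate
  billing does not inflate the count.
- **robust claim** — true if any target-coded claim is inpatient, or two
  target-coded non-inpatient claims fall ≥ 30 calendar days apart
  (inclusive). Clinic claims count as ambulatory here: the rule
  contrasts hospitalization against repeated ambulatory contact.
- **age group** — completed years at the first target-coded claim;
  "18 and younger" means ≤ 18 completed years.
- **specialty flags** — whether a neurologist, or a known non-neurology
  specialist (cardiology, genetics, orthopedics, other), coded a target
  claim. A missing/unknown specialty is its own category and never
  satisfies a specialty predicate.
- **carried-forward neurologic code** — a nervous-system-chapter code
  (numeric root 320–389, excluding the MD codes) on a claim *strictly
  after* the first MD-coded date. The chapter-wide range is a design
  choice; nothing narrower is defensible from the variable's definition,
  and same-day co-coding deliberately does not count.
- **corticosteroid flag** — case-insensitive substring match of
  "prednisone" or "prednisolone" in any in-window fill. The substring
  rule means methylprednisolone matches; the intent is "was a steroid in
  the DBMD standard of care prescribed", and claims drug-name fields are
  too free-form for exact matching.

Persons with no in-window target-coded claim get no feature row at all
(an absent marker), never a zeroed record, so downstream counts cannot
silently treat "unobserved" as "zero".

## The algorithm catalog and its evaluation

The built-in catalog holds one spec per published stratum: any-MD single
code; single 359.21 code; any-MD plus the robust-claim rule; male, ≤ 18,
359.1-coded, robust; neurologist-coded 359.1; other-specialist-coded
359.1; steroid-prescription 359.1; and 359.1 visit tiers at 1, 3, and 10
distinct dates. The male/≤18 stratum's "1 inpatient code or at least 2
outpatient codes" is implemented as the same robust-claim rule (with the
30-day gap) used everywhere else, since the source defines that variable
once. Visit tiers are applied to the unrestricted 359.1-flagged set.
Specialty predicates are limited to {neurology}, the other-specialist
group, or their union — the feature table records exactly those two
flags, and finer filters raise a configuration error instead of silently
approximating.

Reports are one row per (algorithm, target) with target ∈ {any MD,
DBMD, myotonic}; a stratum that flags nobody is an explicit
undefined-accuracy error. The pipeline's bundled report opts into
blank-accuracy rows instead, so one empty stratum on a small cohort
cannot abort an otherwise complete run.

## The logistic predictor models

One binary logistic model per age stratum predicts confirmed status from
intercept, MD-code count, robust claim, male, race dummies (African
American, other; referent white), the two specialty flags, the
carried-forward-code flag, and age in years. Fitting is IRLS (Fisher
scoring) with step-halving, so the log-likelihood is monotone;
convergence requires the score max-norm below `tol·n` with `tol = 1e-8`,
within 50 iterations. Inference is Wald — single-coefficient z against
the standard normal, matching how such models are reported in claims
epidemiology — with an inclusive significance threshold P ≤ .05.
Complete separation is detected (coefficient norm exceeding 40, singular
information, or non-convergence) and raised as an explicit error; there
is no penalized fallback, because a silent remedy would change the
estimand. Rank-deficient designs name the offending columns (an
all-female stratum, for instance, names `male`).

## The synthetic cohort generator

The generator emulates the structural features the analysis relies on;
its defaults are the study conditions where those are stated:

| parameter | default | rationale |
|---|---|---|
| `n_persons` | 4,765 | size of the linked-partition union (537 + 2698 + 1530) |
| `p_true_case` | 0.48 | confirmed fraction among linked code-flagged persons |
| `subtype_mix` (dbmd) | 0.27 | DBMD share of confirmed cases; myotonic 0.18, unknown 0.25 (≈ a quarter of confirmed cases had unknown type), remainder split |
| `overlap` | 537:2698:1530 | both / passive-only / active-only proportions |
| window | 1998-01-01..2012-12-31 | the claims observation window |
| visit means | 5–9 (true), 1.3 / 3.5 (false) | true cases accumulate care; rule-outs are isolated codes |
| code emission | 359.21 rare in false positives | the myotonic code's high specificity |

Each person draws a latent class: a confirmed subtype (dbmd, myotonic,
congenital/other, other MD, unknown) or a false-positive mechanism —
*rule-out coding* (≈ one isolated MD code) or *miscoding* of another
neuromuscular disease (moderate visit count, extra nervous-system-chapter
codes). Conditional on class: a zero-truncated negative-binomial visit
count (dispersion 1.2, truncated at 120 and renormalized); per-encounter
code, setting, and specialty draws; sex, child-onset, race, steroid, and
carried-forward-code Bernoullis. Encounter dates are sampled uniformly
*without replacement* within person, so distinct-date counts equal
encounter counts exactly. Age is planted at the first MD-coded date:
birth date is back-computed so completed years at that date equal the
planted age, with a ≤ 363-day jitter that keeps birth on or before every
claim. Coverage (both/passive-only/active-only) is independent of
everything else; passive tables contain only passive-covered persons and
the gold table only active-covered ones.

Randomness: one master seed spawns twelve named substreams (class,
coverage, visits, per-encounter fields, demographics, prescriptions,
extra codes, …), so extending one table never perturbs another, and the
same (config, seed) reproduces every output byte.

**What the generator does not emulate**: real coding is bursty and
autocorrelated (ours is exchangeable within person); covariates are
conditionally independent given the latent class, so real-world
confounding between, say, specialty access and visit count is absent;
there is no enrollment churn, no death, no ICD-10 era, and no attempt to
match South Carolina demography or absolute statewide counts. Passing
tests therefore demonstrate internal consistency of the pipeline under a
faithful *structural* model, not that the published accuracies would be
recovered on real claims — those depend on the original restricted data.

## The enumeration oracle

`planted_ppv` computes the generator-implied PPV of a catalog algorithm
exactly: mixture over latent classes; zero-truncated NB over the visit
count k; Binomial thinning to the count j of target-coded encounters;
then closed-form predicate probabilities given j — the robust rule uses
the exact discrete range distribution P(range ≤ 29) for j distinct days
drawn from the window (cross-checked in tests against brute-force subset
enumeration), and specialty/steroid/demographic predicates multiply in
as independent Bernoullis. One approximation remains: the age-group
predicate of the male/≤18/359.1 algorithm is judged at the first
*359.1*-coded date in the pipeline but planted at the first *any-MD*
date in the generator, so a person can cross 18 in between; the effect
is well under one empirical standard error at n = 50,000 and is why the
end-to-end check uses a 3-SE band rather than equality.

## Problem sizes and tolerances

The end-to-end recovery and visit-tier checks use one generated cohort
of 50,000 persons (≈ 5,600 linked), where every catalog algorithm flags
≥ 100 persons and binomial SEs are ≈ 0.7–2 percentage points. The
temporal-rule oracle comparison runs 10,000 random claim sets of up to
10 claims over a 10-year span. Regression recovery uses 200 replicates
at n = 5,000 with a fixed seed schedule, requiring each coefficient
inside ±2 estimated SE of its planted value in ≥ 93% of replicates
(nominal Wald coverage ≈ 95.4%); sign recovery for coefficients with
|β| ≥ 0.5 is checked at n = 2,000 over 40 seeds. Accuracy rounding is
half-up (via decimal arithmetic, not float rounding) because the
published percentages are printed half-up at mixed precisions; precision
is therefore a report parameter, 1 decimal by default.

## Known limitations

- Linkage is exact-key only; probabilistic matching is out of scope.
- Code sets are configurable but there is no ICD-9→ICD-10 mapping.
- The published regression coefficients and statewide counts are data
  outcomes of the original restricted datasets; the package reproduces
  the model structure, referents, and inference machinery, and carries
  those numbers only as reference fixtures.
- No steroid dose/duration modeling; no X12/837 claim parsing; no
  capture–recapture prevalence estimation from the overlap counts.
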