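# Methods

This note documents the statistical procedures, the synthetic-data model
behind the test suite, and the numerical and design choices where the
design was genuinely open. It states no empirical result that the tests or
`scripts/acceptance.py` do not themselves compute.

## Disproportionality statistics

All four algorithms operate on the per-drug 2×2 table of unique reports
(a = drug+event, b = event without drug, c = drug without event, d =
neither; N = a+b+c+d). Point estimates and bounds:

| statistic | formula | interval | positivity |
|---|---|---|---|
| ROR | ad/bc | e^(lnROR ± 1.96·√(1/a+1/b+1/c+1/d)) | a ≥ 3 ∧ ROR ≥ 3 ∧ CI low > 1 |
| PRR | (a/(a+b))/(c/(c+d)) | e^(lnPRR ± 1.96·√(1/a−1/(a+b)+1/c−1/(c+d))) | a ≥ 3 ∧ PRR ≥ 2 ∧ CI low > 1 |
| IC | log₂(aN/((a+b)(a+c))) | IC025 = E(IC) − 2√V(IC) | IC025 > 0 |
| EBGM | aN/((a+b)(a+c)) | e^(lnEBGM ± 1.96·√(1/a+1/b+1/c+1/d)) | EBGM05 > 2 |

The BCPNN expectation and variance use the Dirichlet-smoothed closed forms
with derived γ = γ₁₁(N+α)(N+β)/((a+b+α₁)(a+c+β₁)):

    E(IC) = log₂[ (a+γ₁₁)(N+α)(N+β) / ((N+γ)(a+b+α₁)(a+c+β₁)) ]
    V(IC) = (1/ln²2) · [ (N−a+γ−γ₁₁)/((a+γ₁₁)(1+N+γ))
                       + (N−a−b+α−α₁)/((a+b+α₁)(1+N+α))
                       + (N−a−c+β−β₁)/((a+c+β₁)(1+N+β)) ]

Prior defaults are the standard choice for these forms — α=β=2, α₁=β₁=1,
γ₁₁=1 — and are configurable (`BCPNNPriors`). They make E(IC)
prior-centred at independence for an empty table.

Deliberate conventions, each exposed as a switch:

- **EBGM is the observed/expected ratio, not MGPS.** The ratio form
  (identical to 2^IC) with a Wald interval is implemented literally; the
  shrunken multi-item gamma-Poisson estimator is out of scope. EBGM05
  defaults to the two-sided 1.96 lower bound; a flag offers the
  conventional one-sided 1.645 fifth percentile.
- **IC025 is E(IC) − 2√V(IC)**, not a posterior quantile.
- **Zero cells.** When b = 0 or c = 0, a Haldane–Anscombe +0.5 is added to
  all four cells for ROR, EBGM and χ² only, and the output is flagged
  (`continuity_corrected`). The PRR has no continuity variant: with c = 0
  it is reported undefined. With the correction disabled, a zero cell
  raises an error naming the cell.
- **χ²** is the Yates-corrected Pearson statistic (clamped at zero),
  reported alongside the PRR for descriptive completeness; it takes no part
  in the joint rule.
- A signal call is the conjunction of all four positivity criteria — the
  high-specificity convention for screening; single-algorithm verdicts are
  retained per drug with their reasons.
- Reported tables round half-up to two decimals; all internal computation
  is double precision.

## Ingestion and cleaning

Quarterly files are $-delimited ASCII with one header row; headers are
matched case-insensitively, unknown columns ignored, and any data line
whose field count differs from the header is tallied as unparseable rather
than loaded. Cleaning order is deduplication first, then validity
exclusions:

1. **Deduplication**: one version per CASEID, keeping the maximal FDA_DT.
   Ties are broken by the larger primaryid (the later version sequence).
   A caseid whose every version has an unparseable FDA_DT is excluded and
   logged.
2. **Missing drug**: no DRUG row, or every drugname blank.
3. **Missing reaction**: no REAC row.
4. **Missing demographics**: a primaryid present in DRUG/REAC but absent
   from DEMO. Missing sex/age/country never exclude a report — they feed
   the Unknown strata.
5. **Implausible dates**: EVENT_DT strictly earlier than *every* parseable
   START_DT in the report. Requiring all starts (not any) keeps multi-drug
   reports whose later-added drug started after the event.

Date precision: 8-digit YYYYMMDD parses to a date; 6-digit YYYYMM and
4-digit YYYY are retained as raw strings for year counting but treated as
missing for interval arithmetic and the implausibility screen. Every
removal is tallied in a `CleaningLog` whose totals reconcile exactly with
the input count; the invariant is asserted in tests.

Drug-name mapping normalizes (uppercase, trim, collapse whitespace, strip
trailing dose/form tokens from a configurable suffix list) and looks names
up in a two-column alias→generic dictionary in which every generic
self-maps. The default policy excludes a report entirely when any mention
is unmappable (the strict reading of treating such reports as invalid); a
mention-level drop is available for sensitivity analysis. Combination
products map to a single configured generic; salt forms are handled by
dictionary aliases, not stemming, for auditability.

Contingency counting uses the unique report as unit — a report mentioning a
drug several times counts once — and the denominator N is all cleaned,
mapped reports, not only case reports. All drug roles count by default,
with a suspect-only switch (`roles={"PS","SS"}`).

## Time-to-onset

TTO = EVENT_DT − START_DT in days for case reports exposed to the drug,
using the earliest parseable start among the drug's therapy rows (first
exposure). Negative intervals, missing dates and partial-precision dates
are excluded and tallied by reason. Same-day onsets (0 days) are retained
for the median/IQR and shifted to 0.5 day for the Weibull fit only, whose
support is the positive reals.

Quantiles use linear interpolation between order statistics (numpy's
default); fractional quartile bounds in published onset tables imply an
interpolating convention.

The Weibull fit is the two-parameter MLE via the classic profile reduction:
given shape k the scale is λ(k) = (mean xᵏ)^(1/k), and k solves the
monotone score equation Σxᵏln x/Σxᵏ − 1/k − mean(ln x) = 0 by bracketed
root-finding (bracket doubled until the score changes sign, then Brent's
method at 1e-10 tolerance). The shape CI is Wald on the log scale from the
observed information (central-difference Hessian of the log-likelihood in
(log k, log λ), step 1e-5). Onset pattern is early/random/late according to
whether the shape CI lies below, spans, or lies above 1. Censoring is
ignored: spontaneous reports carry no follow-up, so no censoring
information exists in the data model. Degenerate inputs (all values equal)
or a failed bracket return a non-converged fit; the median/IQR summary is
still emitted. The minimum fit size defaults to 10 records.

Note that onset intervals are whole days (the generator rounds up, real
reports carry day precision at best), and day-rounding biases the fitted
shape downward when the scale is short relative to a day — e.g. a planted
shape of 1 at scale 10 days fits near 0.8. The shape recovery guarantees
below are therefore stated for continuous inputs; integer-day fits on
short-scale drugs should be read qualitatively.

An independent cross-check in the test suite compares the profile MLE with
scipy's `weibull_min.fit(floc=0)` on the same data; the acceptance suite
verifies < 5% shape bias at n = 1000 over 200 replicates for true shapes
0.5, 1 and 2, and ≥ 95% correct pattern classification pooled over those
replicates (for a true shape of exactly 1, "correct" means the CI spans 1,
which by construction happens at roughly the CI's coverage rate).

## Synthetic data model

The generator emulates the structures the pipeline must handle, with every
planted feature recorded in a ground-truth sidecar:

- Each report has one background drug drawn uniformly from the background
  pool, plus a Poisson(0.4) number of concomitant background mentions.
  Each signal drug is added independently with its `exposure_prob`.
- The target PT occurs with probability `baseline_event_prob` × (largest
  rate ratio among the report's signal exposures, else 1). Signal exposure
  is independent of background-drug identity, so background drugs are null
  by construction. Every report also carries 1–3 non-target PTs.
- Onset for event reports follows the exposing drug's Weibull law rounded
  up to whole days; therapy starts are placed at EVENT_DT − onset for the
  driving drug and at unrelated earlier dates otherwise, so no clean
  report ever trips the implausibility screen by accident.
- Pathologies are injected disjointly per report (one categorical draw):
  implausible date ordering, blanked drug names, dropped reaction rows,
  dropped demographic rows, or an unmappable drug name — so cleaning
  tallies can be compared to ground truth exactly. Duplicate case versions
  (re-emissions with later FDA_DT and a new primaryid; a tie flag exists to
  exercise the tie-break) and benign missingness (age, sex, event and start
  dates, partial date precision) are drawn independently. Names are
  rendered with mixed case, brand aliases ("BR-" forms present in the
  written dictionary) and occasional dose/form suffixes.
- Default rates (duplicates 5%, date errors 2%, missing drug/reaction
  1%/1%, missing demographics 0.5%, unmappable 2%, brand aliases 30%) are
  of the order seen in raw spontaneous data after quarterly concatenation.

The default `baseline_event_prob` is 0.08. This is a deliberate
desk-scale choice: at the package's simulation sizes (10⁴–5·10⁴ reports) it
gives drug-event cells of the same order as a full-scale screen does, so
threshold behaviour is informative; matching the raw prevalence of any one
PT instead would starve every cell at these sizes.

### The planted-signal study

`signal_study_config` defines the recovery benchmark: 50,000 reports, 50
background drugs, signal drugs at rate ratios 3, 5 and 10 with exposure
probabilities 0.04, 0.008 and 0.004. The exposures come from a power
analysis of the joint rule: the ROR estimates an odds ratio and the EBGM a
marginal observed/expected ratio, both of which sit close to their
thresholds (3 and 2) for a rate-ratio-3 drug, so the weakest signal needs
common-drug exposure for its cells to carry enough information, while the
strong signals are kept rare — as extreme-disproportionality drugs are in
practice — which also bounds their contamination of every other drug's
comparator (the comparator event rate is inflated by a factor
1 + Σᵢ wᵢ(Rᵢ−1) ≈ 1.15 here). Under these conditions each signal drug
passes the joint rule with high probability while the expected
contamination leaves background drugs at odds ratios indistinguishable
from 1.

The recovery check compares the pipeline's ROR for each signal drug with a
99% Monte-Carlo envelope obtained by re-simulating the generator's own 2×2
sampling model (binomial exposure, Bernoulli events at the planted
probabilities) at the retained report count — centred, as the estimator
is, on the true odds ratio implied by the planted rate ratio. Background
calibration is measured over 20 seeds of the same study (1000 drug
screens).

### What the generator does not emulate

Realistic drug co-prescription correlation, the MedDRA hierarchy (a PT
list in configuration stands in for it), report-source (RPSR) content,
schema drift across years, free-text dosage records, and
reporter-dependent differential underreporting. Passing tests therefore
demonstrate correctness of the pipeline's logic under a faithful abstract
model of FAERS's structure, not performance on the full messiness of the
real database — in particular, real signal screens face confounding by
indication and polypharmacy that no independence-based simulation
reproduces.

## Descriptive reporting

Strata: sex and integer-year age bins (≤18, 19–40, 41–64, ≥65, each
boundary inclusive as labelled, plus Unknown) partition the case set;
indications, outcomes (codes mapped to Death/Disability/Life-threatening/
Hospitalization; a report counts once per distinct code) and countries are
top-k lists. All percentages use the total case count as denominator and
round half-up to two decimals; the published table this convention was
checked against contains a few cells that differ by ±0.01–0.02 from their
own printed counts, and the recomputed value is taken as authoritative.
Yearly trends count the FDA receipt year of the retained version (receipt
dates are near-complete; event dates are not). Top-drug rankings emit both
percent-of-all-case-reports and percent-of-top-k denominators, labelled,
since neither convention is universal. The ranked signal table lists
jointly positive drugs by descending ROR with "-" for drugs without usable
onset records.

## Problem sizes

Defaults throughout were chosen so the full test suite and the acceptance
script each complete in minutes on a single CPU: 2,000-report fixtures for
unit tests, the 50,000-report study (21 runs) for recovery and
calibration, 10,000 reports for the cleaning audit, 10,000 random tables
for the ordering identity, and 3×200 replicates at n = 1000 for Weibull
recovery.
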