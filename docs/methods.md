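# Methods

## The measurement problem

There is no billing code for a "skeletal-related event". Observational
studies infer the composite — pathologic fracture (PF), spinal cord
compression (SCC), bone palliative radiotherapy (RAD), surgery to bone
(BS) — from diagnosis and procedure codes on claims, which introduces two
coupled measurement choices: *which codes identify each subtype* and *over
what period repeated claims count as one event*. This package makes both
choices explicit, configurable, and auditable, and quantifies their effect
on prevalence and cumulative incidence.

## Pipeline

### Cohort selection

Inclusion requires, in fixed order: age at diagnosis ≥ 66 (one full year
of Medicare claims before diagnosis), a known diagnosis month, diagnosis
before death, no cancer history in the 5-year washout, continuous
Parts A/B fee-for-service enrollment over the 365 days up to and including
diagnosis (zero-gap coverage of the lookback by the union of enrollment
intervals), and no SRE-coded claim strictly before the diagnosis date.
Only the first failing rule is logged per patient, so the attrition table
is deterministic. The prior-SRE screen uses the union of every tier of
every subtype list: the selected cohort is therefore identical whichever
composite definition is evaluated downstream. Day-of-diagnosis claims
belong to follow-up, not to history.

Follow-up runs from diagnosis to the earliest of four censor dates: first
HMO enrollment on/after diagnosis (an HMO spell already covering diagnosis
censors on the diagnosis day), the first day after the Parts A/B interval
covering diagnosis ends, death, and the administrative study end
(2010-12-31 by default).

### Event identification

Codes are normalized (dots stripped, upper-cased) and matched against a
codebook of patterns — exact codes or `*`-terminated prefixes (`7331*`
matches the whole 733.1x family; a trailing `X` in the conventional
notation is accepted as a synonym, since ICD-9-CM codes never end in X).
Tiers are stored as a SPECIFICITY core plus a disjoint SENSITIVITY_EXT
extension, so the high-sensitivity list is a superset of the
high-specificity list *by construction* rather than by convention.

Events are day-granular: all matching claims of one subtype on one day
merge into a single event-day (claims carry no intra-day ordering), and a
day carrying at least one specificity-tier claim is classified
specificity-tier. Every candidate is retained with a status
(`KEPT` / `EXCLUDED_TRAUMA` / `EXCLUDED_HIERARCHY` / `EXCLUDED_CONCURRENCY`
/ `EXCLUDED_OUTSIDE_FOLLOWUP`) so exclusions are auditable.

**Trauma rule.** A sensitivity-tier ("other fracture") PF event on day *d*
is excluded iff the patient has a non-exempt accident/fall E-code claim in
the closed window [*d* − 14, *d*]. Both boundaries are deliberate: a trauma
claim on the fracture day itself, or exactly 14 days before, excludes; 15
days before does not. Same-level-fall E-codes (E885–E886) are exempt — a
low-energy fall points to bone weakened by tumor — but their presence does
not shield against a distinct non-exempt trauma code in the window. A
fracture day carrying a specific 733.1x code is never trauma-excluded.

**Optional literature variants**, all default-off because the two named
definitions do not impose them: a same-day hierarchy (clinical events PF
and SCC suppress same-day treatment events RAD and BS), a RAD concurrency
filter (RAD kept only with a same-day bone-metastasis/bone-pain/PF/SCC
claim), and a BS trauma lookback using the same closed [*d* − 14, *d*]
window as the PF rule (the published variant says "in the 14 days prior",
which leaves the surgery day ambiguous; one convention is used and stated).

### Episode clustering

Per patient and subtype, sorted event-days are grouped under a window
policy. Default anchoring is `EPISODE_START`: a new event-day joins the
open episode iff it is within `length_days` of the episode's *first* day —
reading "within 21 days of a previous one" as distance from the counted
SRE. `ROLLING` (distance from the most recent event-day) is also provided
because published descriptions rarely state which restart rule was used;
rolling windows can only merge more, so rolling episode counts are ≤
episode-start counts. Boundaries are inclusive (day 0 and day 21 form one
episode at a 21-day window; day 22 starts a new one). Clustering is
strictly within subtype. `brute_force_cluster` is an independent reference
scan used only by the tests.

### Measures and rounding

Prevalence = patients with ≥ 1 kept event ÷ cohort, ×100. Cumulative
incidence = episode count. Per-patient means divide by patients with ≥ 1
episode *of that subtype*; medians over an even count take the midpoint
mean. Percent change between configurations is (b − a)/a × 100 with the
sign kept (negative = decrease); a zero baseline is flagged `None` rather
than raised. The definition comparison is reported in the
alternative → base-case direction. All reported figures round **half-up**
at the printed precision — one decimal for rates and means, integer for
percent changes — via decimal arithmetic, not float banker's rounding.
Count-level helpers (`percent`, `per_patient_mean`, `percent_change`) are
public so published tables of counts can be re-derived without line-level
data.

## Synthetic data

The generator emulates the structure of fee-for-service claims for men 66+
with incident metastatic prostate cancer, 2000–2010 (so the study-end
censor binds): per-subtype episode renewal processes with a minimum
inter-episode gap (60 days by default) and within-episode claim spans of
0–7 days; fracture episodes miscoded to "other fracture" codes with
probability 0.45; trauma and same-level-fall E-code co-claims near
fractures (probability 0.05 each); exponential survival with median 566
days. Default marginal rates {PF 0.40, SCC 0.065, RAD 0.43, BS 0.035}
episodes/patient-year are multiplied by a per-patient gamma frailty
(mean 1, shape 0.5): the overdispersion concentrates events in a
vulnerable minority, which is what lets under half the cohort carry any
SRE while affected patients average ≳ 3 episodes. At n = 1000 the realised
marginals are ≈ 41 % any-SRE prevalence and 3.6–3.8 episodes per affected
patient. Each patient consumes an independent substream
(`SeedSequence(seed, spawn_key=(i,))`), so growing `n_patients` never
reshuffles existing patients.

Two regimes matter for validation:

* **well-separated** (default: gap ≥ 60 d ≫ window ≥ span ≤ 7 d) — no
  window can merge distinct episodes or split one, so identification +
  clustering must recover the ground-truth episode counts *exactly* (and
  does; asserted at n = 500);
* **overlapping gaps** (gap law shrunk below the window,
  `well_separated=False`) — clustering merges true episodes, measured
  incidence under-counts truth, and the bias grows monotonically as gaps
  shrink; this reproduces the direction of the window-length sensitivity
  (longer window ⇒ fewer counted episodes).

What the generator does **not** model: realistic age/race/geography
marginals, comorbidity, claim-setting structure (inpatient vs carrier),
code frequencies beyond a uniform draw within each list, and
non-exponential survival. Passing tests therefore demonstrate correctness
of the measurement logic under known truth, not calibration of the shipped
code lists against real claims — those lists cover only the canonical
codes and are a documented approximation, unvalidated clinically.

## Problem sizes

The test suite and the acceptance script run the full pipeline at 200–1000
synthetic patients and the clustering oracle on 1000 random day-sets under
both anchorings and five window lengths; these sizes give stable
behaviour-level assertions (exact recovery, monotone directions) while
keeping a complete run in the tens of seconds.

## Known limitations

* The shipped codebook names only the canonical members of each list; full
  operational lists are site-supplied.
* "Other fracture" miscoding is all-or-nothing per episode in the
  generator; real coding is messier.
* No cost attribution, comorbidity indices, survival modelling, or
  ICD-10 support.
* A published table occasionally prints a figure that does not reproduce
  from its own printed counts under any standard rounding (e.g. a
  per-patient mean of 6505/2202 = 2.95 printed as 2.9, and 571/8997 =
  6.35 % printed as 6.4 %); the package documents half-up rounding and
  reports what the arithmetic yields rather than chasing such cells.
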