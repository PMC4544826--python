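# skelevent

Measurement of **skeletal-related events (SREs)** from administrative health
insurance claims.

Patients whose cancer has metastasized to bone suffer a composite of four
complications — pathologic fracture (PF), spinal cord compression (SCC),
bone palliative radiotherapy (RAD), and surgery to bone (BS) — that is a
standard endpoint in trials of bone-targeted therapy. Observational studies
must instead infer these events from billing codes, and the estimates they
produce depend heavily on two measurement choices:

1. **Which codes count.** Each subtype has a *high-specificity* code list
   (e.g. the ICD-9-CM 733.1x "pathologic fracture" family) and a
   *high-sensitivity* list that adds less specific codes (e.g. the
   "other fracture" chapter, since clinicians often miscode cancer-related
   fractures). Two composite definitions are built in: **base case**
   (sensitive PF; specific SCC, RAD) and **alternative** (specific PF;
   sensitive SCC, RAD); bone surgery has a single unambiguous list.
   "Other fracture" events are dropped when a non-exempt accident or fall
   E-code appears within the 14 days up to the fracture (same-level falls
   from routine activity are exempt: they suggest bone weakened by cancer,
   not trauma).
2. **How claims group into events.** Claims from one clinical episode are
   spread over days to weeks, so event-days of one subtype within a
   *window* (14, 21 or 28 days; 21 is the clinical-trial convention) are
   clustered into a single SRE episode.

The package implements the full pipeline for a cohort of older men with
incident metastatic prostate cancer — cohort selection with enrollment,
washout and censoring rules; per-day event identification under a chosen
definition; window clustering; and the summary measures:

* **prevalence** — share of cohort patients with ≥ 1 event of a subtype,
  `n_t / N × 100`;
* **cumulative incidence** — total episode count after clustering, with
  per-patient means, medians, and 1/2/3+ distributions;
* **sensitivity comparisons** — percent change of any measure across
  definitions or window lengths, `(b − a)/a × 100`.

Because the linked cancer-registry/Medicare data this design targets is
restricted-access, the package ships a synthetic claims generator with
known ground truth (true episodes, deliberate fracture miscoding, trauma
co-claims) so every stage is testable end to end.

## Worked example

```python
import skelevent as sk

patients, claims, truth = sk.generate(sk.SimConfig(n_patients=500, seed=7))
cb = sk.default_codebook()
cohort = sk.select_cohort(patients, claims, cb)
events = sk.kept(sk.identify_events(claims, cb, sk.make_definition("base_case"), cohort))
episodes = sk.cluster_episodes(events, sk.WindowPolicy(21))

prev = sk.prevalence_table(events, cohort, "base_case")
inc = sk.incidence_table(episodes, cohort)
```

Formatting the two tables (and `sk.truth_episode_counts(truth)`) prints:

```
cohort: 500 patients; 209 (41.8%) with at least one SRE
  PF : 146 patients (29.2% of cohort), 314 episodes at 21d
  SCC:  42 patients (8.4% of cohort),  55 episodes at 21d
  RAD: 153 patients (30.6% of cohort), 355 episodes at 21d
  BS :  17 patients (3.4% of cohort),  18 episodes at 21d
total episodes (21-day window): 742; mean per SRE patient: 3.6
true episode counts: {'PF': 322, 'SCC': 55, 'RAD': 355, 'BS': 18}
```

41.8 % of the simulated cohort has at least one SRE, and affected patients
average 3.6 episodes. Measured PF episodes (314) fall short of the true
count (322): eight miscoded fracture episodes carried a trauma E-code
within the 14-day lookback and were excluded by the trauma rule — exactly
the loss the audit trail (`EventStatus.EXCLUDED_TRAUMA`) attributes. With
the default well-separated generator (episodes ≥ 60 days apart, claims
within 7 days), the three windows agree; shrink
`SimConfig.inter_episode_gap_days` below the window and clustering starts
merging distinct episodes, so measured incidence under-counts truth.

The same pipeline is scriptable from the shell:

```sh
skelevent simulate --seed 7 --n-patients 500 --out data/
skelevent summarize --patients data/patients.csv --claims data/claims.csv \
    --definition base_case --window 21 --out results/
skelevent identify --patients data/patients.csv --claims data/claims.csv --out ev/
skelevent cluster --events ev/events.csv --window 28 --out w28/
```

Every command writes a `manifest.json` (inputs, codebook hash, definition,
window, seed, version); identical manifests reproduce identical outputs.

## Code lists

`skelevent.default_codebook()` loads the shipped
`src/skelevent/data/default_codebook.csv` covering the canonical list
members per subtype plus the accident/fall E-code families. Site-specific
lists can replace it: `sk.load_codebook("my_codes.csv")` with columns
`pattern,system,sre_type,tier,role`, where a trailing `*` (or the
conventional `X`, as in `733.1X`) marks a prefix pattern. The shipped lists
are a documented approximation, not a clinically validated algorithm.

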