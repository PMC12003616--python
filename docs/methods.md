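# Methods

## The classification model

The engine operationalizes the MDS clinical diagnostic criteria for
progressive supranuclear palsy as three sequential operations over a
16-dimensional binary feature profile (O1–O3, P1–P3, A1–A3, C1–C3, CC1–CC4),
optionally annotated with per-feature onset times in months from disease
onset.

1. **Allocation.** The combination table is shipped as data
   (`src/pspmax/data/rules.yaml`): 16 rows, each a phenotype, a certainty
   level and a positive boolean formula stored in disjunctive normal form
   (`any_of` = list of conjunctions). For each of the eight phenotypes the
   engine emits at most one allocation, at the highest certainty whose
   formula the present-feature set satisfies. Matching is *literal*: a
   higher-certainty feature does not stand in for a named lower one (O1 does
   not satisfy a slot that names O2). An optional stratum-subsumption mode
   relaxes this; it is off by default and off in every shipped check.
   Because every formula is negation-free, each phenotype's allocated
   certainty is monotone under feature addition — verified exhaustively over
   all 2^16 profiles.

2. **MAX resolution.** Multiple simultaneous allocations are extinguished
   lexicographically: (rule 1) keep only the allocations at the maximum
   certainty; (rule 2) among ties, keep those with the earliest phenotype
   onset; (rule 3) PSP-RS prevails over any variant. The criteria also name a
   fourth step ("MAX hierarchy, rule 1 prevailing over 2 and 3") which we
   read as a statement of precedence among steps 1–3 rather than an extra
   tie-breaker; strict lexicographic application is what the engine
   implements. A phenotype's onset is defined as the earliest onset among the
   features that satisfied its formula (the criteria invoke "temporal order
   of onset of symptoms" without anchoring it; this is the natural anchor
   given the data the sheet collects). An allocation whose contributing
   features lack any onset has *unknown* onset; unknown ties with unknown and
   never beats a known onset, so absent evidence cannot promote a phenotype.
   Residual variant-vs-variant ties (certainty tied, onsets tied, no PSP-RS)
   fall through to a fixed configured order — PSP-PGF, PSP-P, PSP-F, PSP-SL,
   PSP-CBS, PSP-OM, PSP-PI — chosen descending by the certainty reach of each
   variant's rows and exposed in `data/resolution.yaml`; the criteria print
   no order among variants. Every extinction is recorded with the rule that
   caused it, and the trace narrates each applied step.

3. **Probable 4R-tauopathy.** The final (phenotype, certainty) pair is looked
   up in a total map shipped as configuration. The default is imported from
   the MDS criteria publication (Höglinger et al., Mov Disord 2017): any
   probable diagnosis, or possible PSP-CBS, displays YES. The source paper of
   this tool never prints the membership, so the map is deliberately
   configuration, overridable via `--tau-map`.

## Composite-feature derivation

- **C2 (frontal presentation):** at least 3 of apathy, bradyphrenia,
  dysexecutive syndrome, reduced phonemic fluency,
  impulsivity/disinhibition/perseveration.
- **C3 (corticobasal syndrome):** at least one cortical sign (orobuccal or
  limb apraxia, cortical sensory deficit, alien limb) AND at least one
  movement sign (rigidity, akinesia, myoclonus).
- **A2 vs A3 (levodopa resistance):** resistant iff MDS-UPDRS motor
  improvement (pre − post)/pre ≤ 0.30 under a qualifying regimen (challenge
  ≥ 200 mg, or ≥ 1000 mg daily for ≥ 30 days — "one month" is encoded as 30
  days, the criteria give no day count). Worsening (negative improvement)
  counts as resistant; a zero pre-score or no qualifying regimen is
  *not assessable* and derives nothing. Resistance derives A2; response
  derives A3 and rules out A2 (response does not preclude A3's
  tremor/asymmetry arms).
- **P2/P3 (pull test):** P2 if the patient would fall if not caught; else P3
  if more than two steps backward with unaided recovery; exactly two steps,
  or assisted recovery, derives neither.
- **Temporal gate:** P1–P3 and A1 with a recorded onset beyond the window
  (default 36 months, boundary *inclusive* — the criteria say "within 3
  years" without boundary semantics) are set absent before allocation.
  Features entered as bare 1/0 carry no onset and are trusted as temporally
  valid, matching the flat-sheet entry style; gating is effectively opt-in
  via supplied onsets, and only recorded onsets are gated (a feature first
  recorded late but historically earlier must be entered with its historical
  onset).

When a record supplies both raw observations and an explicit feature flag and
they disagree, the explicit flag wins and a warning is logged: flags are the
sheet's primary input, raw observations a convenience.

Two documented discrepancy readings: Table-level sources state that clinical
clues determine neither certainty nor phenotype, yet the combination table's
suggestive-of PSP-P row lists CC1–CC4 as qualifying partners; the engine
follows the combination table, so clues participate in exactly that one row.
C1 covers both nonfluent/agrammatic PPA and progressive apraxia of speech as
a single code; no sub-distinction reaches the rules.

## Parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| `gate_window` | 36 | months | temporal gate on P1–P3, A1 (inclusive) |
| challenge dose | ≥ 200 | mg | qualifying levodopa challenge |
| sustained regimen | ≥ 1000 for ≥ 30 | mg, days | qualifying sustained levodopa |
| resistance threshold | ≤ 0.30 | fraction | max improvement still resistant |
| `stratum_subsumption` | off | — | higher stratum satisfies a lower slot |
| `tiebreak_order` | PGF, P, F, SL, CBS, OM, PI | — | residual variant tie-break |

## Synthetic data

The cohort generator emulates flat smartsheet-style entry: independent
Bernoulli presence per feature, optional uniform onset draws per feature. The
default prevalences (O1 0.55, O2 0.30, O3 0.15, P1 0.60, P2 0.35, P3 0.15,
A1 0.08, A2 0.30, A3 0.20, C1 0.07, C2 0.40, C3 0.08, CC1–CC4 0.20–0.30) were
chosen once as plausible cross-sectional frequencies for a moderately
advanced PSP clinic population — frequent ocular-motor and postural findings,
rare gait freezing, speech/language and corticobasal presentations. They are
a testing substrate, not an epidemiological claim: real cohorts have
correlated features, progression-dependent prevalence and informative missing
onsets, none of which the generator models. Passing tests therefore
demonstrate the engine's logical fidelity to the published rules on arbitrary
inputs (the exhaustive 2^16 sweeps cover *every* possible profile), not
calibration to any clinical population.

## Numerical and design choices

- All logic is exact boolean/integer work; the only floating-point inputs are
  onsets, dose and score values, compared with plain `<=`/`>` (no tolerances
  needed at the stated thresholds).
- Deterministic tie-breaks everywhere: allocations are resolved in configured
  phenotype order; report serialization sorts keys so identical reports are
  byte-identical.
- A profile satisfying no row is an explicit "no PSP allocation" outcome
  (final = none, 4R = NO), never an error. Exactly 54 of the 65,536 profiles
  are in this class (subsets of {P3, A2, A3, C2, CC1–CC4} that complete no
  row).
- Rules, tauopathy map and tie-break order are data documents validated
  against the feature vocabulary at load time, so criteria corrections need
  no code change; a row naming an unknown code fails loading with the row
  number.
- Problem sizes in the shipped checks: exhaustive sweeps run the full 65,536
  profiles (the cube is small enough that sampling would be a needless
  weakening); the simulated acceptance cohort uses n = 2,000 and the
  frequency-calibration test n = 10,000.

## Known limitations

- The criteria's mandatory inclusion/exclusion criteria and the prodromal
  "suggestive of PSP" category beyond the combination-table rows are not
  operationalized (out of scope, as in the source sheet); imaging findings
  and non-criteria signs (round-the-house, zig-zag, procerus, gunslinger)
  are deliberately absent.
- Each visit is resolved independently; longitudinal synthesis across visits
  is reporting only.
- The MDS-UPDRS item 3.12 ordinal score is not mapped to P2/P3; the engine
  takes the observation-level pull-test outcome instead.
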