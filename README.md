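# pspmax

A scriptable, explainable rule engine for the Movement Disorder Society (MDS)
clinical diagnostic criteria for progressive supranuclear palsy (PSP), built
for clinicians learning the criteria and for batch research use (cohort
labelling, trial pre-screening).

PSP is a rare neurodegenerative 4R-tauopathy. Its clinical diagnosis rests on
four core functional domains — ocular motor dysfunction (**O**), postural
instability (**P**), akinesia (**A**) and cognitive dysfunction (**C**) — each
contributing three features stratified by diagnostic certainty (O1–O3, P1–P3,
A1–A3, C1–C3; 1 highest), plus four clinical clues (CC1–CC4). The criteria's
combination table maps present features to one of eight phenotypes (PSP-RS,
the Richardson-syndrome apex, and seven variants: PSP-P, PSP-PGF, PSP-F,
PSP-OM, PSP-SL, PSP-CBS, PSP-PI) at a certainty level
*probable* > *possible* > *suggestive of*. Each rule is a positive boolean
formula over feature codes, e.g. probable PSP-RS = (O1 ∨ O2) ∧ (P1 ∨ P2).

Because a patient commonly satisfies several rows at one visit, the
**Multiple Allocations eXtinction (MAX) rules** collapse simultaneous
allocations to a single diagnosis, applied lexicographically:

1. highest diagnostic certainty wins;
2. among ties, the phenotype whose qualifying symptoms began earliest wins;
3. among remaining ties, PSP-RS prevails over any variant
   (a configured fixed order breaks residual variant-vs-variant ties).

The final (phenotype, certainty) pair is then mapped to the
**probable 4R-tauopathy** YES/NO category used for joint PSP/corticobasal-
degeneration trial recruitment (default per the MDS criteria: any probable
diagnosis, or possible PSP-CBS).

The package also derives composite features from raw clinical observations:
the frontal presentation (C2, ≥ 3 of 5 items), corticobasal syndrome (C3,
≥ 1 cortical plus ≥ 1 movement sign), levodopa resistance (A2 vs A3,
MDS-UPDRS motor improvement ≤ 30 % under a qualifying regimen) and the pull
test (P2/P3), and applies the criteria's three-year temporal gate to the
time-constrained features P1–P3 and A1.

## Worked example

`cohort.csv` (one row per patient visit; features entered 1/0, onsets in
months from disease onset):

```csv
patient_id,visit_month,o1,o2,o3,p1,p2,p3,a1,a2,a3,c1,c2,c3,cc1,cc2,cc3,cc4,onset_o1,onset_p1,onset_a1
pt-01,12,1,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,10,6,
pt-02,24,1,0,0,1,0,0,1,0,0,0,0,0,0,0,0,0,18,18,4
pt-03,6,0,0,0,0,0,0,0,0,1,0,0,0,1,0,0,0,,,
```

```bash
psp classify --input cohort.csv --output report.json --explain
```

prints (abridged to patient pt-02):

```
Patient pt-02 (visit month 24)
  Features present: O1 (onset 18 mo), P1 (onset 18 mo), A1 (onset 4 mo)
  Allocations:
    - probable PSP-PGF [O1, A1]
    - probable PSP-RS [O1, P1]
    - possible PSP-OM [O1]
    - suggestive of PSP-PI [P1]
  MAX resolution:
    allocations: probable PSP-RS [O1, P1]; probable PSP-PGF [O1, A1]; possible PSP-OM [O1]; suggestive of PSP-PI [P1]
    MAX rule 1 (diagnostic certainty): kept certainty 'probable'; extinguished possible PSP-OM [O1]; suggestive of PSP-PI [P1]
    MAX rule 2 (temporal order of symptom onset): kept earliest phenotype onset (4 months); extinguished probable PSP-RS [O1, P1]
    final diagnosis: probable PSP-PGF [O1, A1]
    probable 4R-tauopathy: YES

Cohort summary
  records: 3
  PSP-P: 1
  PSP-PGF: 1
  PSP-RS: 1
  probable 4R-tauopathy YES: 2
```

pt-02 satisfies four rows at once; MAX rule 1 keeps the two probable
allocations, and MAX rule 2 awards the diagnosis to PSP-PGF because gait
freezing began at month 4, before the Richardson-syndrome features (month 18).
Both probable diagnoses would display probable 4R-tauopathy = YES. pt-03
(parkinsonism A3 plus a clinical clue) reaches only *suggestive of* PSP-P,
which is not a 4R-qualifying category.

Other CLI commands: `psp enumerate --output all.csv` writes the diagnosis for
all 65,536 feature combinations; `psp simulate --n 100 --seed 1 --output
sim.csv` samples a synthetic cohort in the standard schema; `psp rules`
exports the shipped combination table (YAML). The rule table, the
4R-tauopathy map and the tie-break order are data, overridable with
`--rules` / `--tau-map`. The library API (`pspmax.evaluate_allocations`,
`pspmax.resolve_max`, `pspmax.classify_batch`, …) exposes the same pipeline.

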