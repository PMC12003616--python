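# Combination table of the MDS-PSP criteria: clinical feature combinations
# that attribute a phenotype at a level of diagnostic certainty.
#
# Each row names a phenotype, a certainty level, and the qualifying feature
# combinations in disjunctive normal form: `any_of` is a list of conjunctions,
# and a conjunction is satisfied when every listed feature is present.
# Formulas are positive (no negation); the engine relies on that for
# monotonicity. Feature codes: O1-O3 ocular motor, P1-P3 postural instability,
# A1-A3 akinesia, C1-C3 cognitive, CC1-CC4 clinical clues.
rules:
- phenotype: PSP-RS
  certainty: probable
  any_of: [[O1, P1], [O1, P2], [O2, P1], [O2, P2]]
- phenotype: PSP-RS
  certainty: possible
  any_of: [[O2, P3]]
- phenotype: PSP-RS
  certainty: suggestive-of
  any_of: [[O3, P2], [O3, P3]]
- phenotype: PSP-P
  certainty: probable
  any_of: [[O1, A2], [O1, A3], [O2, A2], [O2, A3]]
- phenotype: PSP-P
  certainty: suggestive-of
  any_of:
  - [A2, O3]
  - [A2, P1]
  - [A2, P2]
  - [A2, C1]
  - [A2, C2]
  - [A2, CC1]
  - [A2, CC2]
  - [A2, CC3]
  - [A2, CC4]
  - [A3, O3]
  - [A3, P1]
  - [A3, P2]
  - [A3, C1]
  - [A3, C2]
  - [A3, CC1]
  - [A3, CC2]
  - [A3, CC3]
  - [A3, CC4]
- phenotype: PSP-PGF
  certainty: probable
  any_of: [[O1, A1], [O2, A1]]
- phenotype: PSP-PGF
  certainty: possible
  any_of: [[A1]]
- phenotype: PSP-F
  certainty: probable
  any_of: [[C2, O1], [C2, O2]]
- phenotype: PSP-F
  certainty: suggestive-of
  any_of: [[C2, O3], [C2, P3]]
- phenotype: PSP-OM
  certainty: possible
  any_of: [[O1]]
- phenotype: PSP-OM
  certainty: suggestive-of
  any_of: [[O2], [O3]]
- phenotype: PSP-SL
  certainty: possible
  any_of: [[O1, C1], [O2, C1]]
- phenotype: PSP-SL
  certainty: suggestive-of
  any_of: [[C1]]
- phenotype: PSP-CBS
  certainty: possible
  any_of: [[O1, C3], [O2, C3]]
- phenotype: PSP-CBS
  certainty: suggestive-of
  any_of: [[C3]]
- phenotype: PSP-PI
  certainty: suggestive-of
  any_of: [[P1], [P2]]
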