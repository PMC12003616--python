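# MAX-resolution configuration.
#
# probable_4r_tauopathy: the phenotype/certainty pairs for which the final
# diagnosis displays YES for the joint PSP / corticobasal-degeneration
# trial-recruitment category. The default follows the MDS criteria
# (Hoglinger et al., Mov Disord 2017): any probable PSP diagnosis, or
# possible PSP with predominant corticobasal syndrome. Pairs not listed are NO.
probable_4r_tauopathy:
  probable: [PSP-RS, PSP-P, PSP-PGF, PSP-F, PSP-OM, PSP-SL, PSP-CBS, PSP-PI]
  possible: [PSP-CBS]
  suggestive-of: []

# Residual tie-break order among variant phenotypes, applied only when
# diagnostic certainty, symptom onset and the PSP-RS hierarchy all fail to
# separate the surviving allocations. PSP-RS never reaches this step (it wins
# at the hierarchy step); it is implicitly first.
tiebreak_order: [PSP-PGF, PSP-P, PSP-F, PSP-SL, PSP-CBS, PSP-OM, PSP-PI]
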