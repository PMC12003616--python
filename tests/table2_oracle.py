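"""Independent, deliberately naive evaluator of the combination table.

Each phenotype's certainty rows are transcribed cell by cell from the
published table as literal boolean conditionals over the 16 feature codes —
no data-driven machinery, no shared code with the engine. Used as the oracle
for exhaustive equivalence testing.
"""


def oracle_allocations(present: set[str]) -> dict[str, str]:
    """Map a set of present feature codes to {phenotype: certainty token}."""
    o1 = "O1" in present
    o2 = "O2" in present
    o3 = "O3" in present
    p1 = "P1" in present
    p2 = "P2" in present
    p3 = "P3" in present
    a1 = "A1" in present
    a2 = "A2" in present
    a3 = "A3" in present
    c1 = "C1" in present
    c2 = "C2" in present
    c3 = "C3" in present
    cc1 = "CC1" in present
    cc2 = "CC2" in present
    cc3 = "CC3" in present
    cc4 = "CC4" in present

    out: dict[str, str] = {}

    if (o1 or o2) and (p1 or p2):
        out["PSP-RS"] = "probable"
    elif o2 and p3:
        out["PSP-RS"] = "possible"
    elif o3 and (p2 or p3):
        out["PSP-RS"] = "suggestive-of"

    if (o1 or o2) and (a2 or a3):
        out["PSP-P"] = "probable"
    elif (a2 or a3) and (o3 or p1 or p2 or c1 or c2 or cc1 or cc2 or cc3 or cc4):
        out["PSP-P"] = "suggestive-of"

    if (o1 or o2) and a1:
        out["PSP-PGF"] = "probable"
    elif a1:
        out["PSP-PGF"] = "possible"

    if c2 and (o1 or o2):
        out["PSP-F"] = "probable"
    elif c2 and (o3 or p3):
        out["PSP-F"] = "suggestive-of"

    if o1:
        out["PSP-OM"] = "possible"
    elif o2 or o3:
        out["PSP-OM"] = "suggestive-of"

    if (o1 or o2) and c1:
        out["PSP-SL"] = "possible"
    elif c1:
        out["PSP-SL"] = "suggestive-of"

    if (o1 or o2) and c3:
        out["PSP-CBS"] = "possible"
    elif c3:
        out["PSP-CBS"] = "suggestive-of"

    if p1 or p2:
        out["PSP-PI"] = "suggestive-of"

    return out
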