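"""Classify chronic inflammatory diseases as cancer-prone or not.

Applies the rule  prone ⇔ (RR > 2) ∨ (HR > 2) ∨ (SIR > 1.4)  to the shipped
nine-disease registry of published epidemiological effect sizes, printing
each disease's category.  Diseases reported only through an inverse
association with cancer (Alzheimer's disease, irritable bowel syndrome)
carry a protective flag and are never prone.
"""

from frbinn import classify_registry, reference_registry

registry = reference_registry()
categories, counts = classify_registry(registry)

print(f"{'disease':<32} {'RR':>6} {'HR':>6} {'SIR':>6}  category")
for disease in registry.inflammatory():
    fmt = lambda v: f"{v:.2f}" if v is not None else "-"
    label = "CP-CID" if categories[disease.name] == "prone" else "NCP-CID"
    print(
        f"{disease.name:<32} {fmt(disease.rr):>6} {fmt(disease.hr):>6} "
        f"{fmt(disease.sir):>6}  {label}"
    )
print(f"\n{counts['CP-CID']} cancer-prone, {counts['NCP-CID']} non-cancer-prone")
# The four CP-CIDs are exactly the diseases whose published statistic
# exceeds a threshold; the 5/4 split is the reference categorization.
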