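"""Derive quartile-based PUFA classes for the reference macroinvertebrate taxa.

Loads the packaged 24-taxon table of mean ARA/EPA/DHA mass fractions
(µg/mg dry weight, 25 Finnish lakes), recomputes the quartile class
boundaries over the taxon means, assigns each taxon an ordinal class 1–5 per
fatty acid, and reports where the derived classes differ from the classes
recorded in the table (all such cases sit within rounding distance of a
boundary, because the recorded means are printed with one decimal).
"""

from pufalakes import classify_all, load_reference_profiles

profiles = load_reference_profiles()
result = classify_all(profiles)

print("Quartile class boundaries (µg/mg DW), lower-inclusive intervals:")
for pufa in ("ara", "epa", "dha"):
    b = result.boundaries[pufa]
    print(f"  {pufa.upper():>3}: class 2 < {b.q1:.3f} <= class 3 < {b.q2:.3f}"
          f" <= class 4 < {b.q3:.3f} <= class 5")

print("\nExample assignments (class 5 = PUFA-rich, class 1 = not detected):")
for taxon in ("Amphipoda/Pallasidae", "Odonata/Zygoptera", "Ephemeroptera"):
    p = next(q for q in result.profiles if q.taxon == taxon)
    print(f"  {taxon:<24} ARA {p.class_ara}  EPA {p.class_epa}  DHA {p.class_dha}")

print(f"\n{72 - len(result.mismatches)} of 72 taxon x PUFA cells match the recorded"
      " classes outright; the rest are boundary-rounding cases:")
for m in result.mismatches:
    print(f"  {m.taxon:<24} {m.pufa.upper()}: recorded {m.printed_class}, derived "
          f"{m.derived_class} (mean {m.mean} is {m.distance_to_boundary:.3f} from a boundary)")
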