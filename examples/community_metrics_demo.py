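"""Upscale taxon PUFA classes to community-level response variables.

Simulates a small littoral survey, weights each site's abundance counts by
the taxon PUFA classes, and prints one site's response variables: the five
indices that summarise how much, and how concentrated, the PUFA supply of
the invertebrate community is.
"""

from pufalakes import (
    GeneratorConfig,
    classify_all,
    community_responses,
    generate_survey,
    load_reference_profiles,
)

profiles = classify_all(load_reference_profiles()).profiles
samples = generate_survey(GeneratorConfig(n_lakes=5, seed=42))
site = samples[0]

r = community_responses(site, profiles)
print(f"Site {site.lake_id}/{site.site_id}: {r.richness} taxa, "
      f"{site.total_abundance} individuals per sampling effort")
print(f"{'':14}{'ARA':>10}{'EPA':>10}{'DHA':>10}")
rows = [
    ("Abund_FAwt", r.abundance_fa_weighted, "abundance weighted by PUFA class"),
    ("FA_Abundwt", r.fa_abundance_weighted, "mean PUFA class of an individual"),
    ("FAxAbund", r.fa_x_abundance, "total class-weighted abundance"),
    ("Count>3", r.count_gt3, "taxa in classes 4-5 (PUFA-rich)"),
    ("Count>4", r.count_gt4, "taxa in class 5 only"),
    ("%>3", r.pct_gt3, "share of richness that is PUFA-rich"),
]
for name, mapping, meaning in rows:
    values = "".join(f"{mapping[p]:>10.3g}" for p in ("ara", "epa", "dha"))
    print(f"{name:<14}{values}   # {meaning}")
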