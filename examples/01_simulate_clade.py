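"""Simulate a complete study system and impose realistic missingness.

Builds a 120-species ultrametric clade with nested genera/families,
Brownian-motion body sizes, threshold-model binary traits and block ranges,
then hides trait blocks under a mix of MCAR/MNAR mechanisms with a shared
'poorly known species' factor.
"""

import traitgaps as tg

clade = tg.build_clade(n_tips=120, n_genera=12, n_families=4, n_cells=30, seed=1)
table = clade.traits_true

print(f"tips: {len(table.data)}  genera: {table.data['Genus'].nunique()}  "
      f"families: {table.data['Family'].nunique()}")
print(table.data.head(3).round(2))

spec = tg.MissingnessSpec(
    {
        "body_length": tg.AttributeMissingness("MNAR", rate=0.2, coefficient=-1.0),
        "body_mass": tg.AttributeMissingness("MCAR", rate=0.1),
        "activity": tg.AttributeMissingness("MNAR", rate=0.2, coefficient=1.0),
        "assessed": tg.AttributeMissingness("MCAR", rate=0.15),
    },
    shared_gap_strength=0.5,
)
masked, mask = tg.impose_missingness(table, spec, seed=2)

print("\nhidden blocks per attribute:")
print(mask.sum().to_string())
multi = (mask.sum(axis=1) >= 2).sum()
print(f"species missing two or more blocks: {multi} "
      "(the shared factor concentrates gaps in the same species)")
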