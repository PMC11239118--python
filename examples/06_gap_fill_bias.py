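"""Directional bias of trait knowledge, revealed by gap filling.

Missingness that loads on small-bodied and nocturnal species (MNAR) makes
observed-only summaries overestimate body size and underestimate
nocturnality. Imputing the gaps and recomputing the summaries exposes the
bias as a signed relative change.
"""

import pandas as pd

import traitgaps as tg

clade = tg.build_clade(n_tips=150, n_genera=10, n_families=4, seed=30)
tree, table = clade.tree, clade.traits_true

spec = tg.MissingnessSpec(
    {
        "body_length": tg.AttributeMissingness("MNAR", 0.25, coefficient=-1.0),
        "activity": tg.AttributeMissingness("MNAR", 0.25, coefficient=1.0),
    }
)
masked, mask = tg.impose_missingness(table, spec, seed=31)
print(f"hidden: {mask['body_length'].sum()} body lengths, "
      f"{mask['activity'].sum()} activity blocks "
      "(preferentially small and nocturnal species)")

fs = tg.derive_filters(tg.tree_to_covariance(tree), tree_id="t0")
cfg = tg.ImputationConfig(k_donors=5, m_imputations=3, n_folds=3, seed=32)
filled = tg.multiply_impute(masked, fs, cfg).apply_to(masked)

report = tg.change_report(filled, groupby="Family",
                          attributes=("BodyLength_mm", "nocturnality"))
cols = ["family", "attribute", "property_obs", "property_comb",
        "relative_change", "direction"]
print("\nper-family attribute properties before and after gap filling:")
print(report[cols].round(3).to_string(index=False))
print("\nrelative_change = 1 - comb/obs, so negative values mean the "
      "property ROSE after gap filling;")
print("body size falls and nocturnality rises once the hidden species are "
      "imputed back in.")

grid = tg.per_assemblage_property(filled, clade.assemblages, "nocturnality",
                                  mode="comb")
obs_grid = tg.per_assemblage_property(filled, clade.assemblages, "nocturnality",
                                      mode="obs")
shift = (grid["average"] - obs_grid["average"]).dropna()
print(f"\nassemblage-level mean nocturnality shift: median {shift.median():+.3f} "
      f"across {len(shift)} occupied cells")
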