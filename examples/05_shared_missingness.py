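"""C-score analysis of shared missing data.

Compares a clade whose gaps are independent across attributes with one
whose gaps concentrate in the same poorly known species; the second shows
negative SES C-scores (aggregated missingness).
"""

import traitgaps as tg

clade = tg.build_clade(n_tips=100, n_genera=1, n_families=1, seed=20)
base = {b: tg.AttributeMissingness("MCAR", 0.3) for b in tg.ATTRIBUTE_BLOCKS}

for label, strength in (("independent gaps", 0.0), ("shared gaps", 1.0)):
    spec = tg.MissingnessSpec(dict(base), shared_gap_strength=strength)
    masked, _ = tg.impose_missingness(clade.traits_true, spec, seed=21)
    report = tg.analyze_comissingness(masked, iterations=2000, burn_in=100, seed=22)
    row = report.taxa.iloc[0]
    patterns = report.pairs["pattern"].value_counts().to_dict()
    print(f"{label:17s} median SES = {row['median_ses']:+.2f}   "
          f"pair patterns: {patterns}")
print("\nnegative SES with p < 0.05 = aggregated: the same species miss "
      "several attributes at once,")
print("exactly the situation in which gap filling can shift clade-level "
      "trait summaries.")
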