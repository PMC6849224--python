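"""Fold changes and nonparametric tests for CAP at admission vs controls.

Features are ranked by the ratio of group medians ("fold change"); group
differences use the Mann-Whitney U test with Benjamini-Hochberg FDR
control at 0.05 within the analyte family.
"""

import lipidcap as lc

ds, _ = lc.generate_cohort(lc.default_config(seed=7))
imputed = lc.impute_missing(lc.lod_filter(ds)[0])

table = lc.differential_table(imputed.values, imputed.meta,
                              lc.DEFAULT_CONTRASTS[0])
sig = table[table["p_mwu"] < 0.05]
down = (sig["fold_change"] < 1).sum()
print(f"significant analytes: {len(sig)} / {len(table)}; "
      f"downregulated among them: {down} ({down / len(sig):.0%})")
print(f"FDR-significant: {int(table['reject_fdr'].sum())}")

print("\nmost depressed analytes (fold change, q):")
for name, row in table.tail(5).iloc[::-1].iterrows():
    print(f"  {name:<18s} {row.fold_change:5.2f}  q={row.q_bh:.2e}")
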