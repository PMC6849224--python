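"""Generate a synthetic CAP/COPD/control cohort and inspect its structure.

The generator emulates the study design: 29 pneumonia patients sampled at
admission (d1), days 2 and 4, and two follow-up visits (f1, f2; one
patient lost to follow-up after d4), 13 COPD-exacerbation patients and 33
matched controls sampled once, with 145 lipid analytes and CRP/PCT/acid
sphingomyelinase activity per sample.
"""

import lipidcap as lc

ds, truth = lc.generate_cohort(lc.default_config(seed=7))

print(f"samples: {ds.n_samples}, analytes: {ds.n_analytes}")
print("subjects per group:",
      ds.meta.groupby("group")["subject_id"].nunique().to_dict())
print("CAP samples per timepoint:",
      ds.meta[ds.meta.group == "CAP"].groupby("timepoint").size().to_dict())
d1 = ds.meta[ds.meta["timepoint"].isin(["d1", "single"])]
print("admission CRP medians (mg/l):",
      d1.groupby("group")["crp"].median().round(1).to_dict())
print(f"cells below LOD: {int(ds.mask.to_numpy().sum())} "
      f"({ds.mask.to_numpy().mean():.1%})")
# the truth sidecar records the multiplicative effect each analyte received,
# e.g. the configured admission-day depression of phosphatidylcholines:
pc_truth = truth.effects.loc[("CAP", "d1"), "PC aa C34:4"]
print(f"true PC aa C34:4 effect at admission: {pc_truth:.2f}x control")
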