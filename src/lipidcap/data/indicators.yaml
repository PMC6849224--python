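# Default metabolic indicator set: 11 class sums, 11 class ratios,
# 25 lipid-pair ratios (47 total).  Selectors resolve against the panel;
# explicit pairs reference well-detected analytes so every indicator is
# computable after the detection-fraction filter.  Fully user-editable.

# ---- class sums (11) ------------------------------------------------------
- name: Total PC
  kind: class_sum
  numerator: {class: PC}
- name: Total PC aa
  kind: class_sum
  numerator: {class: PC, bond: aa}
- name: Total PC ae
  kind: class_sum
  numerator: {class: PC, bond: ae}
- name: Total lysoPC
  kind: class_sum
  numerator: {class: lysoPC}
- name: Total SM
  kind: class_sum
  numerator: {classes: [SM, "SM(OH)"]}
- name: Total SM (OH)
  kind: class_sum
  numerator: {class: "SM(OH)"}
- name: Total AC
  kind: class_sum
  numerator: {class: AC}
- name: Total DC-AC
  kind: class_sum
  numerator: {class: AC, moiety: DC}
- name: Total OH-AC
  kind: class_sum
  numerator: {class: AC, moiety: OH}
- name: Total phospholipids
  kind: class_sum
  numerator: {classes: [PC, lysoPC, SM, "SM(OH)"]}
- name: Total PUFA-PC
  kind: class_sum
  numerator: {class: PC, min_double_bonds: 3}

# ---- class ratios (11) ----------------------------------------------------
- name: Total SM/Total PC
  kind: class_ratio
  numerator: {classes: [SM, "SM(OH)"]}
  denominator: {class: PC}
- name: Total lysoPC/Total PC
  kind: class_ratio
  numerator: {class: lysoPC}
  denominator: {class: PC}
- name: SM (OH)/SM
  kind: class_ratio
  numerator: {class: "SM(OH)"}
  denominator: {class: SM}
- name: PC ae/PC aa
  kind: class_ratio
  numerator: {class: PC, bond: ae}
  denominator: {class: PC, bond: aa}
- name: DC-AC/Total AC
  kind: class_ratio
  numerator: {class: AC, moiety: DC}
  denominator: {class: AC}
- name: OH-AC/Total AC
  kind: class_ratio
  numerator: {class: AC, moiety: OH}
  denominator: {class: AC}
- name: Total lysoPC/Total SM
  kind: class_ratio
  numerator: {class: lysoPC}
  denominator: {classes: [SM, "SM(OH)"]}
- name: Total AC/Total phospholipids
  kind: class_ratio
  numerator: {class: AC}
  denominator: {classes: [PC, lysoPC, SM, "SM(OH)"]}
- name: PUFA-PC/Total PC
  kind: class_ratio
  numerator: {class: PC, min_double_bonds: 3}
  denominator: {class: PC}
- name: Saturated PC/Total PC
  kind: class_ratio
  numerator: {class: PC, double_bonds: 0}
  denominator: {class: PC}
- name: MUFA-PC/Total PC
  kind: class_ratio
  numerator: {class: PC, double_bonds: 1}
  denominator: {class: PC}

# ---- lipid-pair ratios (25) ----------------------------------------------
- name: lysoPC a C16:0/lysoPC a C16:1
  kind: pair_ratio
  numerator: ["lysoPC a C16:0"]
  denominator: ["lysoPC a C16:1"]
- name: lysoPC a C20:4/lysoPC a C20:3
  kind: pair_ratio
  numerator: ["lysoPC a C20:4"]
  denominator: ["lysoPC a C20:3"]
- name: lysoPC a C18:1/lysoPC a C18:2
  kind: pair_ratio
  numerator: ["lysoPC a C18:1"]
  denominator: ["lysoPC a C18:2"]
- name: lysoPC a C16:0/PC aa C32:0
  kind: pair_ratio
  numerator: ["lysoPC a C16:0"]
  denominator: ["PC aa C32:0"]
- name: lysoPC a C18:0/PC aa C36:0
  kind: pair_ratio
  numerator: ["lysoPC a C18:0"]
  denominator: ["PC aa C36:0"]
- name: lysoPC a C20:4/PC aa C38:4
  kind: pair_ratio
  numerator: ["lysoPC a C20:4"]
  denominator: ["PC aa C38:4"]
- name: SM C16:0/SM C16:1
  kind: pair_ratio
  numerator: ["SM C16:0"]
  denominator: ["SM C16:1"]
- name: SM C24:0/SM C24:1
  kind: pair_ratio
  numerator: ["SM C24:0"]
  denominator: ["SM C24:1"]
- name: SM C18:0/SM C18:1
  kind: pair_ratio
  numerator: ["SM C18:0"]
  denominator: ["SM C18:1"]
- name: SM (OH) C16:1/SM C16:1
  kind: pair_ratio
  numerator: ["SM (OH) C16:1"]
  denominator: ["SM C16:1"]
- name: PC aa C34:3/PC aa C34:4
  kind: pair_ratio
  numerator: ["PC aa C34:3"]
  denominator: ["PC aa C34:4"]
- name: PC aa C36:5/PC aa C36:6
  kind: pair_ratio
  numerator: ["PC aa C36:5"]
  denominator: ["PC aa C36:6"]
- name: PC aa C38:5/PC aa C38:6
  kind: pair_ratio
  numerator: ["PC aa C38:5"]
  denominator: ["PC aa C38:6"]
- name: PC aa C40:5/PC aa C40:6
  kind: pair_ratio
  numerator: ["PC aa C40:5"]
  denominator: ["PC aa C40:6"]
- name: PC ae C38:5/PC ae C38:6
  kind: pair_ratio
  numerator: ["PC ae C38:5"]
  denominator: ["PC ae C38:6"]
- name: PC aa C34:4/PC aa C36:4
  kind: pair_ratio
  numerator: ["PC aa C34:4"]
  denominator: ["PC aa C36:4"]
- name: PC aa C36:4/PC aa C38:4
  kind: pair_ratio
  numerator: ["PC aa C36:4"]
  denominator: ["PC aa C38:4"]
- name: PC aa C38:4/PC aa C40:4
  kind: pair_ratio
  numerator: ["PC aa C38:4"]
  denominator: ["PC aa C40:4"]
- name: PC ae C36:2/PC ae C38:2
  kind: pair_ratio
  numerator: ["PC ae C36:2"]
  denominator: ["PC ae C38:2"]
- name: C2/C0
  kind: pair_ratio
  numerator: ["C2"]
  denominator: ["C0"]
- name: C16/C0
  kind: pair_ratio
  numerator: ["C16"]
  denominator: ["C0"]
- name: C3/C0
  kind: pair_ratio
  numerator: ["C3"]
  denominator: ["C0"]
- name: C4/C3
  kind: pair_ratio
  numerator: ["C4"]
  denominator: ["C3"]
- name: C18:1/C18
  kind: pair_ratio
  numerator: ["C18:1"]
  denominator: ["C18"]
- name: C18:2/C18:1
  kind: pair_ratio
  numerator: ["C18:2"]
  denominator: ["C18:1"]
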