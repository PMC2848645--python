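{
  "reference_name": "MYH1 skeletal 2x",
  "reference_length": 813,
  "domains": [
    {"name": "beta1", "intervals": [[116, 127]], "category": "core_functional", "group": "beta_sheet_region"},
    {"name": "beta4", "intervals": [[170, 180]], "category": "core_functional", "group": "beta_sheet_region"},
    {"name": "beta6", "intervals": [[248, 257]], "category": "core_functional", "group": "beta_sheet_region"},
    {"name": "beta7", "intervals": [[265, 271]], "category": "core_functional", "group": "beta_sheet_region"},
    {"name": "beta5", "intervals": [[458, 468]], "category": "core_functional", "group": "beta_sheet_region"},
    {"name": "beta3", "intervals": [[671, 678]], "category": "core_functional", "group": "beta_sheet_region"},
    {"name": "sh3", "intervals": [[30, 80]], "category": "core_functional", "group": "sh3"},
    {"name": "switch2_helix", "intervals": [[469, 509]], "category": "core_functional", "group": "switch2_helix"},
    {"name": "sh2_sh1_hinge", "intervals": [[688, 715]], "category": "core_functional", "group": "hinge"},
    {"name": "converter", "intervals": [[716, 772]], "category": "core_functional", "group": "converter"},
    {"name": "lever_arm", "intervals": [[773, 813]], "category": "core_functional", "group": "lever_arm"},
    {"name": "c_loop", "intervals": [[363, 377]], "category": "core_functional", "group": "actin_binding"},
    {"name": "myopathy_loop", "intervals": [[404, 417]], "category": "core_functional", "group": "actin_binding"},
    {"name": "loop2", "intervals": [[626, 651]], "category": "core_functional", "group": "actin_binding"},
    {"name": "loop3", "intervals": [[568, 580]], "category": "core_functional", "group": "actin_binding"},
    {"name": "hydrophobic_actin_contact", "intervals": [[529, 560], [652, 661]], "category": "core_functional", "group": "actin_binding"}
  ],
  "curated_vicinity": [
    {"position": 88, "label": "near beta1", "domain": "beta1", "group": "beta_sheet_region"},
    {"position": 89, "label": "near beta1", "domain": "beta1", "group": "beta_sheet_region"},
    {"position": 98, "label": "near beta1", "domain": "beta1", "group": "beta_sheet_region"},
    {"position": 108, "label": "near beta1", "domain": "beta1", "group": "beta_sheet_region"},
    {"position": 240, "label": "switch1", "domain": "beta6", "group": "beta_sheet_region"},
    {"position": 246, "label": "switch1", "domain": "beta6", "group": "beta_sheet_region"},
    {"position": 258, "label": "between beta6/beta7", "domain": "beta7", "group": "beta_sheet_region"},
    {"position": 445, "label": "near beta7", "domain": "beta7", "group": "beta_sheet_region"},
    {"position": 447, "label": "near beta7", "domain": "beta7", "group": "beta_sheet_region"},
    {"position": 469, "label": "switch2", "domain": "beta5", "group": "beta_sheet_region"},
    {"position": 681, "label": "near beta3", "domain": "beta3", "group": "beta_sheet_region"},
    {"position": 378, "label": "near c_loop", "domain": "c_loop", "group": "actin_binding"},
    {"position": 621, "label": "near loop2", "domain": "loop2", "group": "actin_binding"},
    {"position": 534, "label": "hydrophobic actin contact", "domain": "hydrophobic_actin_contact", "group": "actin_binding"},
    {"position": 655, "label": "hydrophobic actin contact", "domain": "hydrophobic_actin_contact", "group": "actin_binding"}
  ],
  "coarse_regions": [
    {"name": "n_term", "intervals": [[1, 219]]},
    {"name": "u50", "intervals": [[220, 468]]},
    {"name": "l50", "intervals": [[469, 620]]},
    {"name": "c_term_s1", "intervals": [[621, 813]]}
  ],
  "annotations": [
    {"name": "loop1", "intervals": [[200, 220]]},
    {"name": "u50a", "intervals": [[145, 361]]},
    {"name": "u50b", "intervals": [[362, 462]]}
  ],
  "special_tags": {"701": ["swivel"]}
}
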