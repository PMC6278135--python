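"""Generate a synthetic posterior-fossa ependymoma cohort and look inside.

The generator plants the structure every later stage relies on: CpG-island
marker probes drawn from Beta(8,6) in PFA (hypermethylated) and Beta(1,15)
in PFB, arm-level intensity shifts for 1q-gained samples, a three-gene
pyrosequencing panel, and H3K27me3 staining percentages.
"""

from epnmethyl import CohortConfig, generate_cohort

cohort = generate_cohort(CohortConfig(seed=1))

sheet = cohort.sample_sheet
print(f"samples: {len(sheet)} "
      f"({(sheet.subgroup == 'PFA').sum()} PFA, "
      f"{(sheet.subgroup == 'PFB').sum()} PFB, "
      f"{(sheet.subgroup == 'CONTROL').sum()} controls)")
print(f"probes: {len(cohort.annotation)} "
      f"({(cohort.annotation.cpg_island == 1).sum()} on CpG islands, "
      f"{len(cohort.marker_probe_ids)} planted markers)")

pfa = sheet.loc[sheet.subgroup == "PFA", "sample_id"]
pfb = sheet.loc[sheet.subgroup == "PFB", "sample_id"]
markers = cohort.marker_probe_ids
print(f"mean marker beta, PFA: {cohort.beta.loc[markers, pfa].mean().mean():.3f} "
      f"(planted mean 8/14 = {8 / 14:.3f})")
print(f"mean marker beta, PFB: {cohort.beta.loc[markers, pfb].mean().mean():.3f} "
      f"(planted mean 1/16 = {1 / 16:.3f})")
print(f"samples with 1q gain: {int(sheet.has_1q_gain.sum())} (all PFA)")
# The two marker means sit on either side of the 0.5 / 0.2 selection bounds
# the marker-discovery stage must rediscover.
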