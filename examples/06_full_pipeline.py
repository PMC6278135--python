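"""Run every stage end-to-end and print the run report's key numbers.

Equivalent to `epn-methylclass run --seed 11`; the report echoes the full
effective configuration so a run is reproducible from its report alone.
"""

import json

from epnmethyl import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=11))

stages = report["stages"]
print(f"probes: {stages['select_probes']['n_autosomal']} autosomal, "
      f"{stages['select_probes']['n_high_sd_island']} high-SD island, "
      f"{stages['select_probes']['n_subgroup_markers']} subgroup markers")
print(f"clustering agreement with truth: {stages['cluster']['agreement_with_truth']:.2f}")
print(f"1q-gain call accuracy: {stages['cnv']['gain_call_accuracy_vs_truth']:.2f}")
clf = stages["classifier"]
print(f"classifier: mode={clf['selected_mode']}, thresholds="
      f"{ {g: round(t, 1) for g, t in clf['thresholds_percent'].items()} }")
print(f"validation specificity: {clf['confusion']['validation']['specificity']}")
print(f"IHC confusion: {stages['ihc']['confusion']}")
print(f"(full report: {len(json.dumps(report))} bytes of JSON)")
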