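#!/usr/bin/env python
"""Per-species summary table with derived ratios.

Runs the config-driven pipeline on configs/reference.yaml: the three G2
presets carry their published primaries, and a fully synthetic species
(SYNTH-G2) has every primary estimated from generated data.  The derived
columns B = tau_rot/Rg^3 and tau_max/tau_rot are recomputed from the stored
primaries; note that the PPI row recomputes to tau_max/tau_rot = 0.48.

Writes results/reference_run/summary.tsv (plus curve TSVs and run.log).
"""

from dendrorelax.pipeline import run_pipeline

summary, artifacts = run_pipeline("configs/reference.yaml")
print(summary.to_string(index=False))
print("\nartifacts:", ", ".join(sorted(artifacts)) or "none")
print("full outputs in results/reference_run/")
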