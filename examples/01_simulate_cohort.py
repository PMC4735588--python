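"""Simulate a paired relapse/remission cohort with planted effects.

Builds a 13-patient all-female cohort plus 13 controls on a 300-probe array,
plants 10 differentially expressed probes per phase of which 8 follow the
mirror pattern (opposite directions in the two phases vs controls), and
prints the planted truth alongside empirical group-mean fold changes.
"""

import numpy as np

from sncmirror import CohortConfig, simulate_cohort

cfg = CohortConfig(
    n_patients=13, n_controls=13, n_probes=300, sex_ratio=1.0,
    n_de_relapse_f=10, n_de_remission_f=10, n_de_remission_m=0, n_mirror=8,
    effect_log2=2.0, noise_sd=0.3, seed=42,
)
exp, truth = simulate_cohort(cfg)

print(f"cohort: {exp.n_probes} probes x {exp.n_samples} samples")
print(f"planted relapse DE (females): {len(truth.planted('relapse_vs_control', 'females'))}")
print(f"planted mirror probes: {sorted(truth.mirror_set)}")

d = exp.design
rel = exp.intensities[d.index[d.phase == "relapse"]].mean(axis=1)
rem = exp.intensities[d.index[d.phase == "remission"]].mean(axis=1)
ctl = exp.intensities[d.index[d.phase == "control"]].mean(axis=1)
print("\nempirical mean log2 FC vs control (mirror probes flip sign between phases):")
for probe in sorted(truth.mirror_set):
    print(f"  {probe}: relapse {rel[probe] - ctl[probe]:+.2f}  remission {rem[probe] - ctl[probe]:+.2f}")
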