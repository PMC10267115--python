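"""Generate a synthetic cross-over study and write it to disk.

Builds a small drug-vs-placebo resting-state dataset (10 subjects, 8
regions) from the package's linear stochastic network model and serializes
it as plain TSV/CSV/JSON. The printed numbers summarise what a downstream
analysis would load: 2 sessions per subject, a physiological covariate
table, and one behavioural score per subject.
"""

from pathlib import Path

from crossconn import SimulationConfig, generate_study
from crossconn.io import write_study

cfg = SimulationConfig(n_subjects=10, n_regions=8, n_timepoints=120, seed=7)
study = generate_study(cfg)

out = Path("scratch/example_study")
manifest = write_study(study, out)

print(f"sessions: {len(study.sessions)} "
      f"(T={study.sessions[0].n_timepoints}, R={study.sessions[0].n_regions})")
print(f"occipital-like regions: {sorted(cfg.occipital_set)}")
print("covariates:")
print(study.covariates.round(1).head(3))
print("behaviour scores (synthetic subjective-effect ratings):")
print(study.behaviour.round(2).head(3).to_string())
print(f"manifest written to {manifest}")
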