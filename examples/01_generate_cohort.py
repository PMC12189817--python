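"""Generate a synthetic EHR cohort and inspect its structure.

Each patient carries a latent AR(1) health state; 12 of 20 features are
noisy emissions of that state, the rest pure noise; ~30% of entries are
missing; the mortality label follows a logistic link on the terminal
latent state.
"""

import numpy as np

import pathcare as pc

config = pc.SynthConfig(n_patients=500, seed=42)
cohort, truth = pc.generate_cohort(config)

labels = np.array([p.labels["mortality"] for p in cohort.patients])
observed = np.concatenate([p.observed.ravel() for p in cohort.patients])
lengths = [p.n_visits for p in cohort.patients]

print(f"patients:            {len(cohort.patients)}")
print(f"features:            {cohort.schema.n_features} "
      f"({config.n_informative} informative)")
print(f"visits per patient:  {min(lengths)}-{max(lengths)} "
      f"(mean {np.mean(lengths):.1f})")
print(f"missing fraction:    {1 - observed.mean():.3f} "
      f"(target {config.missing_rate})")
print(f"prevalence:          {labels.mean():.3f} "
      f"(target {config.prevalence})")

# the generator retains each patient's true risk: the Bayes-optimal score
oracle = pc.bayes_reference_score(truth, cohort)
scores = np.array([oracle[p.patient_id] for p in cohort.patients])
print(f"oracle AUROC:        {pc.auroc(labels, scores):.3f}  "
      "(ceiling for any model on this cohort)")

paths = pc.write_cohort(cohort, "scratch/example_cohort")
print(f"written to:          {paths['records']}")
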