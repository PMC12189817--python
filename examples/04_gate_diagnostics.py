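"""Inspect the neuron-level filtering gate by outcome group.

The gate is the cumulative softmax of a linear map of the patient's
latest record: a monotone vector from ~0 to 1 splitting the latent
neurons between the task branch (low gate) and the future-predictive
branch (high gate).  Averaging it per patient gives a scalar "how much
does the model lean on future-predictive features for this patient".
"""

import numpy as np

import pathcare as pc

cohort, _ = pc.generate_cohort(pc.SynthConfig(n_patients=800, seed=3))
processed, _ = pc.preprocess(cohort)
params, _logs = pc.fit(
    processed,
    pc.ModelConfig(n_features=20, init_seed=3),
    pc.TrainConfig(seed=3, max_epochs=20, patience=6))

labels = np.array([p.labels["mortality"]
                   for p in processed.patients_in("test")])
diags = [pc.forward(params, b)
         for b in pc.batch_cohort(processed, "test", 256)]
summary = pc.gate_summary(diags, labels)

print(f"mean gate value, adverse outcomes:   {summary.mean_positive:.4f}")
print(f"mean gate value, favorable outcomes: {summary.mean_negative:.4f}")
print(f"difference (adverse - favorable):    {summary.difference:+.4f}")
print("A positive difference means the model allocates more neurons to")
print("future-predictive features for high-risk patients.")

pc.metrics.plot_gate_histogram(summary, labels,
                               "scratch/gate_histogram.png")
print("histogram written to scratch/gate_histogram.png")
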