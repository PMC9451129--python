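"""Train the 7 per-station decoders on a synthetic labeled cohort.

Generates interpretation templates, a labeled explicit-instruction
cohort, fits one logistic classifier per station, and reports held-out
accuracy plus the pilot normalization constants derived from a
free-interpretation pilot cohort.
"""

import numpy as np

from storynf import (
    CohortConfig,
    default_stations,
    estimate_pilot_norms,
    generate_pilot_cohort,
    generate_training_cohort,
    make_templates,
    predict_cheating_probability,
    train_station_models,
)

stations = default_stations()
templates = make_templates(n_features=50, separation=2.0, seed=1)
train_cfg = CohortConfig(n_participants=20, n_runs=2, n_features=50, seed=1)
training = generate_training_cohort(train_cfg, templates, stations)
models = train_station_models(training, regularization_c=1.0)
print(f"trained {len(models)} station decoders on {len(training)} labeled patterns")

heldout = generate_training_cohort(
    CohortConfig(n_participants=20, n_runs=2, n_features=50, seed=2), templates, stations
)
feat = [c for c in heldout.columns if c.startswith("f")]
by_station = {m.station_index: m for m in models}
hits = [
    (predict_cheating_probability(by_station[int(r["station"])], r[feat].to_numpy(float)) > 0.5)
    == (r["group"] == "cheating")
    for _, r in heldout.iterrows()
]
print(f"held-out accuracy: {np.mean(hits):.3f}  (chance = 0.5)")

pilot = generate_pilot_cohort(
    CohortConfig(n_participants=10, n_runs=4, n_features=50, seed=3),
    templates, stations, models,
)
norms = estimate_pilot_norms(pilot)
print("\npilot normalization constants (station, bias, mu, sigma):")
for st, m, s in zip(stations, norms.mu, norms.sigma):
    print(f"  station {st.station_index}  bias {st.bias:+.1f}  "
          f"mu = {m:.3f}  sigma = {s:.3f}")
print("\nStations with a stimulus bias toward one interpretation show a")
print("shifted pilot mean p(c); the score transformation subtracts exactly")
print("this station-wise bias before feedback is delivered.")
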