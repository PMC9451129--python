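"""One participant's closed-loop neurofeedback session.

A compliant, well-decoded agent assigned to the paranoid group runs
4 runs x 7 stations: probe, pattern, decode, normalize, flip, threshold,
reward, update.  Watch the latent lean theta move toward the assigned
interpretation.
"""

import numpy as np

from storynf import (
    AgentState,
    CohortConfig,
    ExperimentConfig,
    build_assets,
    compute_payout,
    decoding_accuracy,
    run_session,
)

cfg = ExperimentConfig(
    n_features=50,
    separation=3.0,
    training=CohortConfig(n_participants=20, n_runs=2),
    pilot=CohortConfig(n_participants=10, n_runs=2),
    seed=5,
)
stations, templates, _, models, _, norms = build_assets(cfg)

state = AgentState(theta=0.0, learning_rate=0.25, snr=2.0)
log = run_session(
    "sub-01", "paranoid", state, models, norms, templates, stations,
    timing=cfg.timing, seed=5,
)

print("run  mean p(c)  mean reward  probes(paranoid)")
for run in (1, 2, 3, 4):
    ev = [e for e in log.events if e.run == run]
    n_para = sum(e.probe_choice == "paranoid" for e in ev)
    print(f"  {run}     {np.mean([e.p_c for e in ev]):.3f}       "
          f"{np.mean([e.score_reward for e in ev]):.3f}         {n_para}/7")

print(f"\nfinal theta: {log.final_state.theta:+.2f}  "
      "(-1 = fully paranoid, +1 = fully cheating)")
print(f"decoding accuracy: {decoding_accuracy(log):+.3f}  "
      "(mean p(c) at cheating-probes minus paranoid-probes)")
print(f"session payout: ${compute_payout(log.events):.2f} of $20.00 cap")
print("\nAn agent assigned 'paranoid' is rewarded when its decoded p(c)")
print("falls below the pilot mean; rewards reinforce the declared lens,")
print("so theta drifts negative and probe choices follow.")
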