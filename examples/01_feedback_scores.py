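"""The feedback score transformation, step by step.

Builds pilot norms for one station and shows how a decoded cheating
probability p(c) becomes the displayed score and the delivered reward
for each assigned group.
"""

import numpy as np

from storynf import PilotNorms, apply_group, normalize_score, threshold_reward

norms = PilotNorms(mu=np.full(7, 0.60), sigma=np.full(7, 0.08))
station = 3

print("station 3 pilot reference: mu = 0.60, sigma = 0.08")
print(f"{'p(c)':>6} {'score_c':>8} {'cheating':>9} {'paranoid':>9} "
      f"{'reward(c)':>10} {'reward(p)':>10}")
for p_c in (0.40, 0.60, 0.66, 0.72, 0.90):
    sc = normalize_score(p_c, norms, station)
    fc, fp = apply_group(sc, "cheating"), apply_group(sc, "paranoid")
    print(f"{p_c:6.2f} {sc:8.3f} {fc:9.3f} {fp:9.3f} "
          f"{threshold_reward(fc):10.3f} {threshold_reward(fp):10.3f}")

print()
print("At p(c) = pilot mean the score is exactly 0.5 and nobody is paid:")
print("feedback rewards deviation from the average interpretation")
print("trajectory in the assigned direction, not the absolute decoded state.")
print("The two groups' scores always sum to 1 (complement symmetry), and")
print("scores <= 0.5 deliver a reward of 0.")
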