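# Methods

`storynf` simulates a closed-loop ("decoded neurofeedback") experiment in
which listeners of an ambiguous story are nudged, via intermittent monetary
feedback computed from multivoxel decoding, toward one of two incompatible
interpretations — *cheating* or *paranoid*. Every component of the loop is
implemented and testable without any neuroimaging data: neural patterns are
replaced by a low-dimensional generative model whose geometry carries the
same information the decoders would see in practice.

## Pattern model

Two interpretation templates `T_c`, `T_p` in `R^d` (default `d = 100`) are
built from a seeded standard-normal base vector split along a random unit
direction `u`: `T_{c,p} = base ± (Δ/2) u`, so `‖T_c − T_p‖ = Δ` (the
*separation*, default 2.0). A participant in interpretation state
`θ ∈ [−1, +1]` (+1 fully cheating) listening at a station with stimulus bias
`b ∈ [−1, 1]` emits

```
x = (T_c + T_p)/2 + (b + snr·θ)·(Δ/2)·u + ε,   ε ~ N(0, I)
```

The expected projection of `x` on the discriminant axis is linear in `θ`
with slope `snr·Δ/2`; `snr = 0` yields patterns carrying no interpretation
signal, which is the degenerate case several tests rely on. Station biases
default to `linspace(−0.6, 0.6)` across the 7 stations, emulating the
observation that free listening leans strongly toward one interpretation at
many points of the story regardless of the listener.

Assumptions this model makes deliberately: isotropic Gaussian noise, a
single discriminant direction shared by all stations, no temporal
autocorrelation, no nuisance structure (motion, drift, physiological
noise). It reproduces the *geometry* that decoding and normalization
operate on, nothing else; passing tests therefore validate the pipeline's
arithmetic and logic, not its robustness to real BOLD noise.

## Cohorts

* **Training cohort** (default 20 participants × 2 runs): the stand-in for
  the previously collected explicit-instruction dataset the decoders are
  trained on. `θ` is pinned at ±1 by assigned label. Station biases are
  *omitted* here: under explicit instruction the instructed interpretation
  dominates the response, and it is precisely the mismatch between this
  training distribution and free listening that makes the pilot means
  shifted at biased stations — the phenomenon pilot normalization corrects.
* **Pilot cohort** (default 10 participants × 4 runs): free-interpretation
  agents with `θ ~ Uniform(−1, 1)` held across runs, scored by the trained
  decoders and pooled across both conditions to give the per-station
  normalization constants `μ_st`, `σ_st`. The population SD (ddof = 0) is
  used by default because the pilot serves as a fixed reference
  distribution; `sd_mode="sample"` is available. A station with `σ_st = 0`
  raises an error rather than silently scoring 0.5.
* **Real-time cohort** (default 20 participants, 10 per group, 4 runs × 7
  stations): closed-loop agents with per-participant `snr ~ U(0.2, 2.0)`
  and `learning_rate ~ U(0.05, 0.4)`, emulating the wide spread of
  decodability and compliance across real participants.

## Decoders and feedback

One L2-regularized logistic-regression classifier per station (lbfgs,
`C = 1`, tolerance 1e−10) outputs `p(c)`, the cheating-interpretation
probability; the paranoid probability is exactly `1 − p(c)`. The feedback
transformation is

```
score_c      = (p(c) − μ_st) / (3 σ_st) + 0.5, clipped to [0, 1]
score_final  = score_c (cheating group)  |  1 − score_c (paranoid group)
score_reward = score_final if score_final > 0.5 else 0
```

The 3σ scaling maps ±1.5 pilot SDs onto the full display range; a
participant at the pilot mean scores exactly 0.5 and earns nothing in
either group. An exact 0.5 is *not* rewarded (the rule is "≤ 0.5 → 0").
Monetary payout distributes a $20 cap uniformly over the 28 stations
(`reward × cap/28` per station); the per-station dollar mapping is a
package choice, as only the cap is a design constant.

Timeline arithmetic uses a 1.5 s TR: analysis windows are the on-screen
station windows shifted 3 TRs (4.5 s) for hemodynamic lag, and feedback
appears one further analysis TR later — 4 TRs (6 s) after station end. The
probe lead (4 s before the station) and the station-start delay after the
probe (2 s) are independent config fields because the two stated lead times
are not mutually consistent; the timeline reports probe onset from the 4 s
lead. Runs are 480 TRs (~12 min).

## The participant agent

No observable model of how listeners integrate feedback exists, so the
closed loop is driven by a minimal reinforcement agent:

* **Probe policy**: `P(cheating) = logistic(θ / τ)`, temperature `τ = 0.5`
  by default; `τ → 0` reports `sign(θ)` deterministically.
* **Lens adoption**: during a station the agent emits from the blended
  state `(1 − a)·θ + a·sign(choice)` with adoption weight `a = 0.5`.
  Declaring a lens and then listening through it is what makes probe-locked
  decoding meaningful; with `a = 0` probes are cheap talk, rewards are
  independent of the declared lens at `θ = 0`, and the loop converges to
  the assigned interpretation only at chance (the first rewarded random
  choice sets the lean). With `a = 0.5` the reward rate is genuinely higher
  for assigned-direction choices, and in simulation 50/50 high-SNR agents
  converge to the assigned lens.
* **Update**: after the feedback display (station end + 4 TRs),
  `θ ← clamp(θ + learning_rate · reward · sign(choice))`; zero reward
  leaves `θ` unchanged.

All randomness flows from one seed per participant through named
substreams (patterns, probes, questionnaire), so sessions reproduce
bit-for-bit.

**Yoked control**: the delivered (and paid) reward at each station is a
same-group donor's reward for that station; when the donor declared the
other lens there, the donor's value is still delivered and the event is
flagged `yoked_fallback`, keeping sessions complete and auditable. The
participant's own `p(c)` and scores are logged alongside, so decoding
accuracy remains computable. In the full-experiment yoked mode, donors are
the same cohort's live sessions, rotated within group.

## Questionnaire model

27 comprehension items (4-option single choice, correct with probability
0.9 independent of `θ` — the free-text grading of real questionnaires is
out of scope), 12 interpretation items coded ±1 with
`P(cheating-consistent) = (1 + θ)/2` per item, and 1–5 empathy ratings with
means `3 + 1.5θ` (Arthur), `3 − 1.5θ` (Lee), `3 − θ` (Joanie), `3` (the
girl), Gaussian jitter (SD 0.5), rounded and clipped. One interpretation
item (the girlfriend-name question everyone is told the answer to) is
flagged excluded and never enters the score, leaving 11 scored items. The
interpretation score is the mean ±1 code; "correct" scores multiply
paranoid-group values by −1, and the empathy contrast is Arthur − Lee with
the same correctness transform.

## Analysis conventions

* **Decoding accuracy**: mean `p(c)` over cheating-probe stations minus
  mean over paranoid-probe stations, pooled across runs. Undefined when a
  label was never chosen; such participants are flagged and excluded from
  accuracy-based statistics, never silently dropped.
* **Median split**: within each assigned group, ranked by
  (accuracy descending, participant id ascending) for a deterministic
  tie-break; top half is "best" (5 + 5 for a 10/10 cohort). Odd group
  sizes require an explicit `odd_policy`.
* **t-tests**: pooled-variance Student tests (`df = n1 + n2 − 2`, e.g.
  `t(18)` for 10 vs 10), one-tailed on request. Pearson correlations use
  the t-transform p-value. Bonferroni families default to 7 for
  station-wise tests within a run and 4 for run-wise tests. SEM bars use
  per-group n, with participant as the unit of analysis (event values are
  averaged within participant before cell statistics).

## Problem sizes and numerical choices

Tests and the acceptance script run reduced but structurally complete
configurations — typically 10–50 feature dimensions, training cohorts of
20–100 agents, pilot cohorts of 5–500, and Monte-Carlo checks of
3,000–10,000 draws with 3-standard-error bands; replicate-cohort properties
use 20 cohorts × 20 agents. Logistic fits use tolerance 1e−10 (the
objective is convex, so fits are deterministic); probability, t-test and
correlation routines are verified against brute-force oracles at 1e−10 to
1e−12. Scores are kept at full precision internally; dollar rounding
happens only at the I/O layer.

## Known limitations

The agent model is a stand-in: its parameters (adoption, learning rate,
temperature) are not estimable from any published data, so simulated effect
sizes — e.g. the strength of the decoding-accuracy ↔ correct-interpretation
correlation — are properties of the chosen study conditions, not
predictions about human cohorts. The pattern model omits all temporal
structure, so nothing here tests real-time preprocessing, registration or
timing robustness. Comprehension answering is independent of
interpretation state by construction, so comprehension analyses only
exercise bookkeeping.
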