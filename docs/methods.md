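# Methods

## Model overview

`seirja` couples two agent-based processes on one undirected network of
`N` individuals:

1. an information-dissemination process with four compartments —
   uninformed (S), silent (E), communicating (I), immune (R) — whose
   transitions are driven by each agent's communicating willingness and a
   forgetting clock rather than fixed probabilities;
2. a bounded-confidence opinion process of the Jager-Amblard family
   (attraction inside `d1`, repulsion outside `d2`, indifference between)
   with per-agent susceptibility built from three heterogeneity factors:
   embeddedness of the interacting tie, conservatism of the receiving
   agent, and its running conformity toward the positive or negative camp.

The two processes interlock: only communicating agents initiate
encounters, every encounter moves attitudes and recognition, and those in
turn decide who keeps communicating, who falls silent and who disengages.

### One simulation step

At step `t`, every agent communicating at the step's start, in a random
order, picks one uniformly random neighbour `j`:

- **immune `j`** — nothing happens;
- **uninformed `j`** — `j` draws an attitude from the initial
  distribution, starts its receipt clock at `z = 1`, sets balanced
  mainstream degrees `w± = 0.5` and recognition `m = 1`, and becomes
  communicating if its willingness (`P = |x|` at `m = 1`) reaches the
  communication threshold `p`, silent otherwise; the pair then interacts;
- **silent or communicating `j`** — the pair interacts directly.

An interaction first shifts both parties' mainstream degrees by `γ`
toward the sign of the opinion each observes, then forms the
susceptibilities `μ = (1 + E_ij)(1 − T)(C^±)` (conformity toward the
sign of the partner's attitude; `x = 0` counts as positive) and applies
the bounded-confidence update simultaneously from the pre-interaction
attitudes, clipping to [−1, 1]. Attitude changes are immediately visible
to later encounters in the same step (sequential within-step updates).
Finally the initiator's recognition moves by ±1 for an
assimilative/repulsive outcome (see "Recognition dynamics" below).

At the step's end, willingness `P = (|x| − 1)e^(1−m) + 1` is recomputed
for every informed agent and compartment transitions are applied
synchronously: to immune when `P < 0` or `z > z0`, silent→communicating
when `P ≥ p`, communicating→silent when `P < p`. Receipt clocks then tick
for all informed, non-immune agents.

A run stops when the step's total squared attitude change is at most
`stop_tol`, checked from the second step onward, or at `max_steps`.
Uninformed agents carry a baseline attitude of 0 in that sum, so a newly
informed agent's drawn attitude counts as change; without this, the early
steps of a run — when conformity is still zero and attitudes barely move —
would satisfy the stop condition immediately and no dissemination
dynamics could ever unfold.

## Parameters

| name | meaning | default | notes |
|---|---|---|---|
| `d1`, `d2` | assimilation / rejection thresholds | 0.3 / 0.7 | strict inequalities; equality is neutral |
| `p` | communication threshold on willingness | 0.5 | |
| `T0` | mean conservatism | 0.8 | per-agent `T_i = N·T0·k_i⁻¹/Σk_l⁻¹`, clipped to [0, 1] |
| `γ` | mainstream-degree step per encounter | 0.1 | `γ = 0` freezes conformity (control setting) |
| `z0` | attention span, steps | 70 | `z > z0` forces immunity |
| `init_comm_frac` | initially communicating fraction | 0.1 | |
| `attitude_mean`, `attitude_sd` | initial attitude normal, truncated to [−1, 1] | 0, √0.3876 ≈ 0.6226 | see "Attitude spread" |
| `N` | population | 300 | 500 in the case-study scenario |
| `stop_tol` | stop-condition tolerance | 0.1 | |
| `max_steps` | horizon cap | 200 | guarantees halting under perpetual rejection |
| `polar_threshold` | extremity cutoff | 0.8 | polarizability counts `|x| > 0.8`, strictly |
| network | family and shape | BA, `m_attach = 25` | WS `k = 48`, rewiring 0.1; ER `p = 49.61/299` |

The baseline values reproduce the published study conditions where those
are printed (`d1`, `d2`, `p`, `T0` and the case-study settings) and use
sweep midpoints where only a swept range is printed (`γ`, `z0`). The
network families are parameterized to a common scale (300 nodes, average
degree ≈ 46–50); the BA attachment count 25 is chosen to hit that scale.

## Readings chosen where the model family leaves details open

Several mechanisms are under-determined in this model family; the package
fixes one reading each, switchable where noted, and these choices were
validated against the published aggregate outcomes (compartment peaks,
full vs bounded polarization, orderings):

- **Mainstream before susceptibility.** Within an encounter the
  mainstream degrees update *before* `μ` is formed. Both parties update
  by default (`both_update_mainstream=False` restricts to the initiator).
  With the opposite order, conformity — initially zero for everyone —
  would gate every first encounter to `μ = 0` and the stop condition
  would end every run at once.
- **Recognition dynamics** (`recognition_scope`, default `"initiator"`).
  Recognition `m` moves ±1 per assimilative/repulsive encounter for the
  *initiating communicator*: it is the agent actually broadcasting, so
  endorsement and rejection feedback accrue to its opinion. The
  symmetric `"both"` reading makes silent agents convert to communicators
  after a single assimilative contact, which inverts the silent /
  communicating peak structure (measured: peaks ≈ 62/170 instead of the
  expected ≈ 150/110 at N = 300). `m` is unbounded below by default so
  that collapsing recognition can push willingness negative and open the
  immunity-by-rejection path; `recognition_floor=1.0` restores the
  declared `m ≥ 1` range at the cost of that path.
- **Attitude spread.** The initial-attitude notation `Normal(0, 0.3876)`
  is read with the standard `N(μ, σ²)` convention, i.e. a *variance*
  (sd ≈ 0.6226); the case-study periods' `N(·, 0.4)` likewise
  (sd ≈ 0.6325). Under the sd reading the silent peak overshoots its
  published band (≈ 185 vs ≈ 150 ± 20%); under the variance reading both
  compartment peaks land inside their bands.
- **Range clipping** (`clip_ranges`, default on). Conformity `2w − 1` and
  `μ = (1+E)(1−T)C` are clipped into their declared [0, 1] ranges
  (raw values can reach −1 and 2 respectively).
- **Conformity step** `ω` **in the case study.** The per-period
  "conformity responsiveness" indices 40, 45, 50, 55 are mapped to
  `γ = 8/ω` ∈ {0.2, 0.178, 0.16, 0.145}: inverse in ω (so conformity
  responsiveness falls over consecutive periods, as the case study
  argues) and anchored so the first period uses the top of the analysed
  γ range. The plainer `γ = 1/ω` reading (≈ 0.02) leaves the coupled
  model far below its published 50–80% final-polarization band (measured
  ≈ 33% in every period), so it cannot be what produced those results.
- **Edge cases.** Embeddedness of a mutually-sole-neighbour pair is 1;
  otherwise `n_ij/((k_i−1)+(k_j−1))` including when exactly one degree is
  1. Isolated nodes get `T_i = T0` (inert — they never interact).
  Newly informed agents draw from the same initial attitude distribution
  as seed communicators. Each communicator initiates exactly one
  encounter per step but may be selected as a partner any number of times.

## Baselines

- **Classic SEIR**: fixed probabilities — every contacted uninformed
  agent accepts (probability 1 by default), silent→communicating with
  0.3, communicating→immune with 0.2 per step; one contact per spreader
  per step on the same networks, synchronous bookkeeping, run to
  absorption. The one-step transition distribution is verified against
  exhaustive enumeration on small graphs (χ² over 10⁴ samples).
- **Classic J-A**: no compartments; every agent holds an attitude from
  step 0 and has one encounter per step with fixed `μ = 0.5` on both
  sides. With equal coefficients an assimilative encounter conserves the
  pair mean exactly (the Deffuant-Weisbuch property, used as a test
  oracle with `d1 ≥ 2` and attitudes off the walls).

## Ensembles and experiment sizes

All headline quantities are 10-run Monte-Carlo ensembles with a fresh
network per run; series are aligned by carrying shorter runs forward at
their final value, and the ensemble relative standard deviation
(sample SD / mean per time point, zero-mean points skipped, averaged over
time) is reported as a stability index. The standard batteries sweep the
initial communicator fraction {0.05, 0.1, 0.15, 0.2}, `z0`
{50, 70, 90, 110}, `p` {0.2, 0.4, 0.6, 0.8}, `T0` {0.2, 0.4, 0.6, 0.8}
and `γ` {0.05, 0.1, 0.15, 0.2}, the `T0 × γ` grid read at steps
{10, 20, 40, 70}, and the BA/WS/ER comparison at matched average degree.
At these sizes (N = 300–500, ≤ 200 steps, 10 runs) every battery
completes in seconds on one CPU.

## The synthetic comment stream

Real per-comment platform data cannot be redistributed, so the
case-study scenario runs against a synthetic stream generated by the
package itself (`seirja.fixture`; every such object is labelled
synthetic). A fixture-scale simulation (200 agents) produces raw comment
events — each communicating agent emits one comment per step with
sentiment = attitude + Normal(0, 0.1) noise, clipped to [−1, 1] — which
are then resampled to the requested per-period totals: comment count,
distinct-user count and first-three-hours share exactly, first-3-hours
mean sentiment within ±0.02 by re-centering, timestamps uniform within
their day at hourly resolution. The stream therefore has model-plausible
temporal structure (early burst, spread, rising extremity) and the
published summary statistics, but it is *not* real data: the daily
activity profile beyond day one, the within-day arrival pattern and the
user-activity distribution are artifacts of the generator. Comparisons
against it (e.g. the RMSE table of the case-study scenario) validate the
machinery, not the models' empirical fit, and the package makes no claim
about reproducing published RMSE-vs-real-data values.

## Known limitations

- **Network comparison ordering.** The published account expects the
  small-world (WS) network to polarize least at matched scale. In this
  implementation the WS ensemble robustly polarizes *most* at
  N = 300 / average degree ≈ 48: at that density every family's
  clustering is ≥ 0.17 and WS's is always the highest, so its
  embeddedness — and hence susceptibility — is systematically larger,
  while in the BA network roughly a third of the nodes (degree below the
  harmonic mean) sit at the conservatism clip `T = 1` under `T0 = 0.8`
  and never move at all. The slow-spreading disadvantage attributed to
  small worlds cannot bind in graphs of diameter ~2. The comparison and
  its ordering statistic are implemented and reported; the expected
  ordering does not emerge under this model reading at this scale, and
  the corresponding check is left failing rather than adjusted.
- The recognition update law and the ω mapping are reconstructions (see
  above); both are config-exposed so alternative readings can be run.
- Compartment transitions use strict/non-strict comparisons exactly as
  specified (`P ≥ p` promotes, `P < p` demotes, `z > z0` forgets);
  behaviour at exact threshold equality is therefore convention, not
  substance.
- The model has no agent turnover, no directed or weighted ties, no
  multidimensional opinions and no platform/government interventions.
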