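# Methods

## State space and transition rules

Each network component holds a qualitative state in {0, 1, 2}: below
control, at control (the unstimulated level), above control. The state
of an unclamped node changes one level at a time, driven by the signed
influence of its regulators:

```
influence(i, t) = Σ_edges(j→i)  sign(j→i) · (s_j(t − d_{j→i}) − 1)
```

with `sign = +1` for activation, `−1` for inhibition, and `d` the
edge's delay in steps. A positive sum shifts the node up (saturating at
2), a negative sum shifts it down (saturating at 0), and a zero sum
lets the state decay one level back toward control — a node whose
regulators are all at control, or that has no regulators, relaxes to 1.

The single-regulator behavior is the specification of the rule: an
activator above control pushes its target up, an inhibitor above
control pushes it down, inactive regulators let the target decay. How
multiple regulators combine is a modeling choice; we use the signed sum
of `(state − 1)` contributions because it reduces exactly to the
single-regulator rules, is symmetric around control, and makes the
competing-regulator case (one activator and one inhibitor both at 2)
resolve to decay rather than to an arbitrary priority. The same
symmetry implies that an activator *below* control contributes −1
(withdrawal of a basal drive) and an inhibitor below control
contributes +1 (de-repression). These completions are not forced by
biology; they are the minimal symmetric extension, and they matter for
knockout semantics (below).

## Asynchronous updating

One time step is one full pass over the unclamped nodes in a fresh
uniform-random permutation, with every update realized immediately:
nodes later in the pass see, at lag 0, the states already updated
earlier in the same pass. Randomizing the order across steps and across
runs encodes the assumption that relative reaction rates differ from
cell to cell, without committing to any particular rate. A fast
cascade can therefore traverse several layers within one step under a
favorable order, and one layer per step in the worst case.

## Delays

A delay-`d` edge makes its target read the regulator's state `d` steps
back, taken from the snapshots committed at step boundaries (never
mid-pass), so the dynamics are history-dependent rather than Markovian.
Two conventions fix the semantics completely:

* **Pre-stimulation history is control.** Delayed reads that reach the
  initial row or earlier return 1. The initial condition marks the
  instant of stimulation; what a slow process "remembers" from before
  stimulation is the control state, not the sampled initial scatter.
  Consequently a delay-`d` edge from a stimulus clamped high leaves its
  target at baseline for exactly the first `d` steps.
* **Delays are lagged reads, not virtual relay nodes.** A chain of
  ordinary one-step relay nodes would implement the same nominal lag
  only in the worst-case update order: a favorable permutation could
  propagate the signal through the whole relay chain within a single
  step, destroying the minimum-latency guarantee the delay exists to
  impose. Lagged reads give the exact, order-independent latency and
  implement the history-dependent formulation directly.

## Ensembles

A run is one cell. An ensemble draws `n_runs` independent cells, each
with its own initial state and its own sequence of update orders, and
reports the per-node, per-step mean and standard deviation. Defaults:
`n_runs = 5000`, horizon 40 steps.

Initial states are scattered around control: each ordinary node starts
at 0 with probability `p`, at 2 with probability `p`, at 1 otherwise,
so the expected initial state is exactly 1. The spread is a free
population-heterogeneity parameter; the default `p = 0.1` keeps the
population centered at control while leaving visible heterogeneity, and
is exposed in every scenario file.

Run `r` of an ensemble draws from a counter-based substream seeded with
`(master_seed, r)`, so results are bit-exactly reproducible, and the
identity of run `r` does not depend on how many runs precede it. The
engine advances all runs of an ensemble in lockstep with the per-run
substream discipline intact; the sequential single-run path and the
ensemble path are verified against each other bit-for-bit in the test
suite, and both against an independently written brute-force
interpreter by exact enumeration on small networks.

`replicate_dispersion` quantifies sampling noise as the largest
disagreement between the mean curves of independently seeded replicate
ensembles; it shrinks as `1/sqrt(n_runs)`, and at 5,000 runs the
residual disagreement on the bundled models is ≈ 0.03 state units —
small enough that differences between perturbation conditions reflect
the wiring, not the sampling.

## Perturbations and constraints

* **Stimulus**: an input node held at a fixed level for the whole
  window (palmitate at 2).
* **Constraint**: a measured invariance encoded by clamping a node at
  its observed level (PP1 at control), which severs its dynamic
  feedback while keeping the graph intact.
* **Knockout**: gene silencing modeled as clamping at 0 — below-control
  activity, not node removal — so delayed edges and influence sums
  through the node's neighborhood stay well defined. Under the signed
  sum a knocked-out activator actively withdraws basal drive
  (contribution −1), which is the intended silencing semantics.
* **Pathway deletion**: removal of a specific interaction
  (`delete_edge`), distinct from knocking out its source node.

Re-clamping an already fixed node is an error, never silent last-wins.
Comparisons between conditions report raw mean differences with pooled
Monte-Carlo standard errors; no hypothesis-testing machinery is
attached, since simulation noise is controlled by `n_runs`, not by
sample-size statistics.

## The palmitate model suite

The bundled networks encode ATF4-dependent ER-stress signaling under
palmitate in liver cells, at the level of arcs named in the primary
literature: palmitate activates the PACT–PKR and PERK arms converging
on eIF2α phosphorylation; eIF2α drives ATF4 (translational, delay 1);
ATF4 induces GADD34, which activates PP1, which dephosphorylates eIF2α
(the negative feedback); palmitate also activates PKA (late), which
drives CREB1 both directly and by inhibiting PP2A, and the
Ca²⁺–calmodulin arm plus p38 and Ras shortcuts also converge on CREB1.
The refined versions add CREB1→ATF4 and ATF4→ATF4 promoter feedback and
drop the dispensable arms.

Two wiring decisions are this package's own:

* **Kinase adaptation arms.** The measured kinase activations are
  pulses, not steps: PKR phosphorylation is prompt and early, PERK
  follows, and the downstream eIF2α profile is transient. With a
  persistently clamped stimulus, a bare activation chain can only
  produce sustained activation, so each palmitate-responsive kinase arm
  carries an explicit desensitization arm — an incoherent feed-forward
  loop from the stimulus through a slower inhibitor (TRBP for PKR,
  p58IPK for PERK, both documented inhibitors of their kinase). The
  onset delay of the inhibitor sets the pulse width; because the
  inhibitor then balances the activator exactly, the kinase settles
  back to control without oscillating.
* **Slow feedback maturation.** The ATF4→GADD34 transcriptional step
  carries a long delay, so the PP1 feedback matures late and the
  suppression of eIF2α (and hence of ATF4, to below control) appears at
  the late end of the window — matching the observed late "inhibited"
  ATF4 profile in the delay-refined model, and vanishing when PP1 is
  clamped at control.

Delay calibration (10 steps ≈ 6 h; this constant is axis metadata only
and never enters the dynamics). All delays are free calibration
parameters exposed in the model files:

| edge | delay | rationale |
|---|---|---|
| PA→PACT(→PKR) | 0 | prompt response, active by ~3 h |
| PA→TRBP ⊣ PKR | 8 | ends the PKR pulse before ~6 h |
| PA→PERK | 5 | PERK onset ~3 h after PKR |
| PA→p58IPK ⊣ PERK | 15 | ends the PERK pulse by ~10 h |
| PA→PKA | 35 | PKA activation near 24 h |
| eIF2α→ATF4 | 1 | translational control, fast |
| ATF4→GADD34(→PP1) | 22 | feedback matures in the second half of the window |
| CREB1→ATF4 | 8 | transcription, slower than translation |
| ATF4→ATF4 | 2 | autoregulatory promoter feedback |

`v1_literature` is the same wiring with **all** delays at 0 (every arm
on one time scale); the adaptation arms then cancel their kinases
within a step or two, reproducing the observed flat eIF2α/ATF4 response
of the unrefined model. Because the original literature network is
ambiguous about whether the PACT–PKR arm was present at all,
`v1_literature_nopkr` ships the variant without it; both satisfy the
same qualitative surface. `v2_delays` differs from v1 only by delay
edits, `v3_pp1_const` adds the PP1 clamp, the two `v4_feedback_*`
versions add one promoter-feedback edge each, and `v5_essential` drops
p38/Ras, GADD34/PP1 and keeps both feedbacks — the version diffs are
audited structurally in the test suite.

## Trajectory classification

A mean trajectory is labeled from two checkpoints (early, step 5;
final, last step) with an elevation threshold of 0.2 state units:
`sustained` (elevated at both), `transient` (elevated early, not at the
end), `suppressed` (≤ 0.8 at the end without early elevation),
`unchanged` (otherwise). "Elevated" in the qualitative surface means
sustained or transient. The threshold and checkpoints are exposed
because the underlying observations are qualitative curve shapes; the
defaults sit far from the realized means (which cluster near 0, 1 and
2 at 5,000 runs), so the labels are not threshold-sensitive.

## Numerical choices

States are int8; ensemble means and standard deviations are computed
in float64 directly from the full run array (no streaming
approximation; the arrays are a few MB). Zero influence is a strict
tie and decays; there are no stochastic tie-breaks anywhere — all
randomness lives in initial states and update orders. Degenerate
inputs: a network of only clamped nodes steps identically; an
unregulated node decays to control in one step; horizon must be ≥ 1;
`n_runs` ≥ 1; the initial spread must lie in [0, 0.5).

## Problem sizes

The test suite runs the full figure suite at the default 5,000 runs ×
40 steps; engine-vs-enumeration checks use networks of ≤ 3 ordinary
nodes at horizon 3, where the exact distribution over all initial
states and update orders is enumerable (≤ 6³ order sequences × 27
initial states), compared at 50,000 runs by chi-square on the
trajectory distribution and a 3-standard-error band on means.
Dispersion scaling is measured on a single-node toy network at
ensemble sizes 50/500/5,000.

## Limitations

Three states cannot express graded dose response or partial knockdown;
one-level-per-visit transitions tie the time axis to network depth;
the signed sum weights all regulators equally (a strong and a weak
activator are indistinguishable); delays are integers in units of the
update step; and the ensemble mean emulates only the population
average of a perfectly synchronized, noiselessly measured population —
no measurement noise, no cell division, no stimulus pharmacokinetics.
The qualitative surface the suite verifies (which versions give
transient/sustained/suppressed responses and how knockouts reorder
ATF4) is robust to these simplifications; absolute state values and
exact transition steps are not quantitative predictions.
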