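# Methods

## The paradigm and its geometry

Stimuli are unit cubes on a 3-row × 13-column lattice in Unity scene units.
Column centres are the cumulative sums of the gap sequence
1, 1, .25 × 8, 1, 1, re-centred so the grid midline is x = 0; the middle
three columns (±0.25 and 0) are presented twice per row per round, all
others once, giving 48 presentations per round over 39 distinct cells. Rows
sit one unit apart, row 1 lowest. The scene's absolute centre (x = 4) is
retained only for re-centring raw logs on ingest; every analysis is
midline-relative.

Four reference frames are linked by pure rescalings: 1 Unity unit = 2.4 cm
on the laptop screen (`visual2D`); `virtual3D` shares the screen scale and
adds the simulated depth between the hand start plane and the stimulus
plane (5.37 cm by default) on the z axis; `real3D` multiplies screen
centimetres by the gain factor 4 — the rounded ratio of the physical hand
separation (22.1 cm) to the mean on-screen hand separation (5.53 cm) —
giving 9.6 cm per Unity unit horizontally. Conversions are bijective,
composable, and sign-preserving; data files store full precision and only
the human-readable report rounds (Unity to 4 decimals, cm to 2).

Reach distances from the nearer start square to a cube centre are computed
planar on the screen, with depth added in quadrature for `virtual3D` and
the ×4 gain for `real3D`. The apparatus' published per-target distances are
not all consistent with a single start geometry or a single depth (the
bottom-middle 4.2 cm screen reach implies a 3.17 cm vertical offset that
rows 2–3 then contradict; the middle-column virtual distances imply
per-target depths between 4.8 and 5.5 cm). We therefore keep the measured
values verbatim in a lookup table (`PRINTED_REACH_CM`) — they are inputs,
used as-is for the ×4 gain step — while the geometric function anchors its
default start geometry to the bottom-middle reach and is relied on only
for its invariants (monotonicity in row, frame scalings, depth degeneracy).

## The RFM estimator

Per subject, row and weight condition, touched-stimulus positions are
averaged separately per hand and the midpoint of the two hand means
estimates the reaching frequency midline. Decisions a raw definition leaves
open, and our defaults:

* **Range normalization.** The percent-of-range variant divides by the
  horizontal stimulus range; we use the centre-to-centre span (6 units) by
  default, configurable to the edge-to-edge 7. Both the midpoint (primary)
  and the normalized value are reported.
* **Degenerate cells.** If a hand is never used in a cell the midpoint is
  missing and the cell flagged; an optional policy imputes the unused
  hand's mean at that hand's outermost column (±3). Degenerate cells are
  excluded from group averaging.
* **Repeated presentations** contribute once per trial (trial-weighted
  means), not once per distinct position.
* **Hemispace assignment** uses the sign of the stimulus centre; the x = 0
  column belongs to neither hemispace for crossover and ipsilateral
  statistics.
* **Group values** are means of subject midpoints (consistent with SEMs
  over subjects), not pooled-trial estimates.

Start-position maps use per-subject 2D histograms (0.25 cm bins, half-open
edges) normalized to 1 per hand, averaged unweighted across subjects.

## Inference

The per-subject 3 × 2 midpoint table enters a within-subject ANOVA computed
by explicit sum-of-squares decomposition (subject, height, weight,
interaction, and matched effect-by-subject error strata) — deliberately not
delegated to a fitting library, so the arithmetic can be checked against an
independent contrast-projection oracle; pingouin serves as a second,
test-only cross-check. Mauchly's test runs per multi-level effect (height,
interaction) on the orthonormal-contrast covariance; Greenhouse–Geisser
epsilon multiplies both degrees of freedom when the corresponding Mauchly
p < .05. The 1-df weight effect cannot violate sphericity. Numerically
zero strata (all cells equal) report F = 0, p = 1 rather than 0/0.

Paired contrasts average over the other factor per subject and use the
textbook paired t with a Bonferroni threshold 0.05/m (0.0167 for the three
height pairs). The exploratory correlation matrix takes 13 variables — EHI
index, grip left/right/difference, the six RFM cells, and the three per-row
weighted-minus-non-weighted differences — yielding 78 Pearson coefficients
with t-transform p-values (n − 2 df) and threshold 0.05/78 = 0.000641.

EHI scoring drops the unreliable broom item (position configurable, last by
default) and computes 100·(R − L)/(R + L) over the remaining 12 items'
tallies; inclusion requires an index above 74 (the 4th right decile).
Manual exclusion flags carry free-text reasons.

## The synthetic cohort

The generative model exists because no raw participant data is public; its
defaults are the published group conditions wherever those exist.

* **Choice.** P(right) = λ/2 + (1 − λ)·logistic((x − m)/σ). The switch
  point m is the generative counterpart of the RFM. Group means per
  row × condition are the published Unity values (NW: −0.1240, −0.2257,
  −0.2125 bottom→top; W: −0.2255, −0.2568, −0.2838); between-subject SDs
  are the published SEMs × √27. A subject's six cells share a common trait
  component (correlation 0.9 across cells): preference is stable within a
  person, and the published within-subject contrast SEMs (an order of
  magnitude below the cell SEMs) are impossible without strong cell-wise
  correlation. Slope σ = 0.5 units and lapse λ = 0.02 are configuration
  values chosen so simulated group crossover totals land in the published
  ~270/330 range; they are not published quantities.
* **Kinematics.** Movement time follows Fitts' law,
  MT = a + b·log₂(2D/W) with a = 0.2 s, b = 0.15 s/bit (conventional
  magnitudes; no kinematic fits are published), D the real-space reach and
  W the cube width; the left hand is slowed by a subject-specific factor
  (mean 1.15) in weighted blocks. Trajectories are minimum-jerk
  (10τ³ − 15τ⁴ + 6τ⁵) sampled at 20 Hz from the jittered start (truncated
  normal, SD 0.25 cm, inside the 2.3 cm start squares) to a uniform point
  in the target cube. Onsets chain exactly 2 s after the previous contact.
* **Covariates.** EHI indices are drawn from a normal (92.02, 8.6)
  truncated to the published 80.77–100 range and realized as 12 item
  responses (plus a discarded broom item); grip strength uses the published
  left-hand moments (39.6 ± 10.7 kg) and left-minus-right difference
  (−3.6 ± 4.0 kg). The right-hand marginal SD implied by this construction
  (≈11.4 kg) slightly exceeds the published 10.4; we prioritize the
  difference moments because the difference enters the correlation matrix.
* **Randomness.** One master seed; per-subject/per-block streams derived by
  counter-based splitting, so results are independent of simulation order.
  Trials are conditionally independent given subject parameters — the
  published record gives no trial-to-trial dependence structure.

A vectorized choice-only path (`simulate_rfm_midpoints`) reproduces the
per-cell midpoint estimator without trajectory synthesis and drives the
calibration studies (2,000-cohort type-I check, 500-cohort power check);
a test verifies its agreement with the full trial-level pipeline.

## What the simulation does and does not establish

The midpoint estimator is a shrunken, nonlinear function of the generative
switch point: with σ = 0.5 the expected midpoint is roughly half of m
(e.g. m = −0.1874 → −0.091), because each hand's mean is dominated by the
far columns it always owns. Parameter recovery is therefore judged against
the exact enumeration expectation over the 16-presentation column multiset,
not against m itself.

More consequentially, the boundary columns (±0.25) are near coin flips
under any moderate slope, putting an irreducible floor (≈0.12 units per
cell at 32 trials) on the estimator's sampling noise. Real participants
were evidently far more deterministic: their published condition-difference
SEM (0.06 cm real-space) is about a third of the floor our logistic policy
admits while still producing published-scale crossover counts. No
logistic-with-lapse setting matches both, so the defaults keep the
crossover calibration and accept reduced sensitivity: the weight-effect
rejection rate under the defaults cohort is ~0.35–0.40 (reported by the
acceptance script, never hard-coded), well above the null rate (~0.05,
verified within [0.03, 0.07] over 2,000 cohorts) but below the certainty
the original cohort's cleaner behaviour afforded. Passing tests therefore
demonstrate estimator and inference correctness and directional effects,
not that real data would yield the original p-values.

Problem sizes used by the shipped checks — 27 subjects × 4 × 48 trials for
pipeline runs, 2,000/500 replicate cohorts for calibration, 10,000 and
12 × 1,000 trials for estimator convergence — were chosen so the whole
suite remains a minutes-scale run on a single core.

## Known limitations

* No biomechanical arm model, no perceptual/attention model, and no
  handedness-development component; trajectories are analysed only through
  the cm/s score.
* The published per-target `virtual3D` distances cannot be regenerated from
  one depth parameter; they are honoured as inputs, not modelled.
* Whether the original score used screen or 3D path length is unstated; the
  score defaults to screen centimetres with a configuration switch.
* The 13-variable correlation set is a documented default; the original
  enumeration of variables is not fully specified.
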