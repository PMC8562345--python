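# Methods

This note documents the measures, the synthetic-session generator, the
numerical conventions, and the open design choices behind `behavdyn`.

## Session model

A session is a uniformly sampled trajectory (t, x, y) at 5 Hz (dt = 0.2 s)
in a rectangular arena with named landmarks, plus an ordered event log of
commodity deliveries (each with a limited-availability window, default
3 s) and head entries, plus metadata (subject, condition, deprivation
sequence, session number). Coordinates are in cm with the origin at the
arena's lower-left corner. Two canonical arenas are built in: a
100 × 100 cm open field with a central dispenser, and a 92 × 92 cm chamber
with food and water dispensers at the centers of opposing walls.

Parsing policy: single-frame tracking dropouts are forward-filled from the
last valid sample (they are common in video tracking); a run of more than
25 consecutive missing frames (5 s) invalidates the session rather than
fabricating a path. Out-of-bounds coordinates are clamped to the boundary
and counted. Event times are real-valued seconds; alignment to frames
happens in the downstream operations.

## Measures

**Kinematics.** Traveled distance is the sum of Euclidean step lengths;
maximum velocity is the largest per-frame step divided by dt. Distance to
a landmark is reported absolutely (cm) or relative to the farthest arena
corner from that landmark, so 1.0 means "as far as the arena allows" —
this normalizer makes sessions comparable across arena sizes. Smoothing is
a trailing (causal) moving average, default 200 frames = 40 s, with
partial windows at the series start so length is preserved. The location
at a delivery uses the sample at or before the onset; at 5 Hz the
approximation error is at most 0.2 s, so no interpolation is done.

**Occupancy.** The zone grid is G × G (default 10), row-major ids, bins
half-open except the closed far edges. Entropy is Shannon entropy of the
occupancy distribution in bits (base 2; a base change only rescales by a
constant). Between-session divergence is Jensen–Shannon (base 2) by
default: unlike raw KL it is defined on the empty zones every real session
has, is symmetric, and is bounded in [0, 1], matching the "close to zero /
far from zero" reading the measures are used for. A KL option with
additive 1/Z pseudocount smoothing is available
(`session_divergence(..., method="kl")`).

**Recurrence.** The recurrence structure of the zone series is summarized
without materializing the T × T matrix: the recurrence rate is
Σ_k n_k(n_k − 1) / (T(T − 1)) from the per-zone frame counts (identical to
the off-diagonal density of the matrix), permanence is the mean length of
maximal constant-zone runs, and the transition count is the number of
frame-to-frame zone changes. Permanence and transition count are this
package's quantification of what recurrence plots show qualitatively as
solid blocks vs checker patterns; the matrix itself is materialized only
for plotting, downsampled to ≤ 1500 × 1500 cells (summaries always use the
full series). No time-lag bound is applied: all T × T frame pairs count.

**Discrete-response indices.** The coincidence index counts a delivery as
covered if at least one sampled frame lies within the coincidence radius
(default 10 cm) during [onset, onset + 3 s]; at 5 Hz no dwell-time
threshold is imposed (a minimum-dwell-frames option exists, default 1, and
an onset-only variant is available since presence-at-onset vs
presence-during-window is a genuinely open reading). Intensity, precision,
and proportion-contacted follow their definitional ratios per
subject–dispenser; undefined ratios (no deliveries, no entries, an
all-zero count series) are reported as missing, never as 0. The percentile
filter computes the p-th percentile (default 5) by linear interpolation
between order statistics and drops values strictly below it; it never
removes the series maximum.

**Feature tables.** 7 features for the single-dispenser design (traveled
distance, entropy, divergence, max velocity, coincidence index, mean
relative distance to dispenser, session number), 13 for the two-dispenser
design (relative distances to food/water dispensers and center, entropy,
divergence, intensity/precision/proportion per dispenser, session,
sequence coded 1/2 as a single binary factor). Divergence of session s
pairs sessions s − 1 and s within subject; session 1 is masked missing.
Rows with any masked feature are excluded from the multivariate stage
(ranking, t-SNE, PCA) but retained for univariate summaries. The mean
distance feature is the relative-mode mean; absolute cm is emitted
alongside as metadata.

**Machine-learning stage.** Continuous features are discretized
equal-frequency into k = 4 bins (quantile cuts, duplicates merged) before
scoring; the discretizer is a convention choice, so k is configurable.
Information gain and Gini gain are computed from the contingency table
directly; χ² is Pearson's statistic without continuity correction. Rank
ties break by feature name for determinism. t-SNE uses PCA initialization,
perplexity min(30, (n − 1)/3) (auto-shrunk with a warning), and an
explicit seed; K-means takes the best of 10 seeded restarts, and agreement
with condition labels is reported as purity (primary) and adjusted Rand
index (chance-corrected, secondary). The PCA projection standardizes
features, fixes each component's sign so its largest-magnitude loading is
positive, and reports per-feature loading vectors for biplots.

## Synthetic-session generator

The generator's defaults are the study conditions the analysis targets:
20-min sessions under FT 30 s or VT 30 s with 2 subjects per condition and
20 sessions per subject (single-dispenser design), and 30-min sessions
under concurrent FT 30 s FT 30 s with 6 subjects × 2 deprivation
conditions × 3 sessions in two sequence orders (two-dispenser design).
VT intervals are drawn from an exponential with mean 30 s (constant
hazard), rejection-resampled into [5, 90] s; the real generators used for
VT schedules (e.g., Fleshler–Hoffman series) differ in interval spectra,
so results sensitive to the interval law should be read with that caveat.

The agent is a discrete-time two-mode process. In **explore** it diffuses
(σ√dt per-frame noise, reflecting walls), optionally pulled toward a
random per-session home base; a hazard governs switching into
**approach**, an exponential contraction toward the goal dispenser at gain
λ (1/s). Under FT the hazard rises sigmoidally as the schedule clock nears
the next delivery (anticipation); under VT/concurrent schedules it is
constant. Reaching the dispenser zone starts an exponential **dwell**;
contacting a delivery refreshes the dwell clock. Head entries are emitted
per frame with fixed probability inside the entry radius. Approach gain is
multiplied by a geometric acquisition ramp (default 1.03/session),
emulating progressively sharper approach across sessions without claiming
a learning mechanism. Child seeds derive from the master seed per
(condition, subject, session) via `SeedSequence` spawn keys, so corpora
are byte-reproducible and extending a design never reshuffles earlier
sessions.

Condition presets and what they encode:

| preset | key settings | intended phenomenology |
|---|---|---|
| FT | λ = 1.2, σ_explore = 6, anticipation hazard 0.35/s over a ~6 s lead, no home base | clock-timed commuting to the dispenser; extended routes; broad, session-stable occupancy |
| VT | λ = 0.5, σ_explore = 3.5, constant bout hazard 0.12/s, home pull 0.25/s toward a random per-session base | local, home-based occupancy that relocates between sessions |
| FD | bout hazard 0.10/s, P(food goal) = 0.85, dwell 6 s | concentration at the food wall |
| WD | bout hazard 0.18/s, P(food goal) = 0.35, dwell 4 s, σ_explore = 4.5 | back-and-forth alternation between dispensers, wider wander |

These settings were calibrated once, before freezing, to the directional
contrasts the designs are known for: FT > VT in traveled distance,
entropy, and maximum velocity; VT > FT in between-session divergence;
food-deprived subjects closer to the food dispenser and water-deprived
closer to the water dispenser, with matching intensity asymmetries; and
the deprivation asymmetry is produced by different bout-alternation
hazards, not gains alone. The parameter-recovery sweep uses approach gains
(0.03, 0.06, 0.12, 0.24, 0.48) /s with common random numbers across gain
levels: in this range arrival time is gain-limited, so the coincidence
index rises and mean dispenser distance falls monotonically; above
~0.5 /s the anticipation-probability ceiling, not the gain, binds and the
sweep would plateau. At the largest step the distance effect (~0.005
relative units over 10 sessions/point) is close to residual path noise,
so isolated step inversions can occur at some seeds; the acceptance script
reports the monotone step fraction rather than a boolean.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: body orientation, gait, rearing/grooming,
wall-following (thigmotaxis), tracking noise and identity swaps, and
inter-individual variability beyond seed noise. One known divergence from
the empirical pattern: mean distance to the arena center comes out
approximately equal across deprivation conditions here (both conditions
dwell at wall dispensers), whereas the empirical studies report it higher
under water deprivation; no analysis in this package depends on that
contrast.

## Numerical conventions and degenerate inputs

Timestamps must be strictly increasing with constant step within 1e-6 s.
Occupancy distributions must sum to 1 within 1e-9. Zone binning places
boundary values in the upper bin (half-open bins, closed far edges).
Entropy uses 0·log 0 = 0. Single-frame series have recurrence rate 1 by
convention. A constant feature standardizes to zeros with a warning
rather than NaN. Purity of k = 1 clustering equals the majority-class
share. All stochastic stages (schedule draws, agent noise, t-SNE,
K-means) consume explicit seeds recorded in the outputs; pipeline CSVs
carry the config hash and seed in a header comment.

## Problem sizes

The shipped analyses run the full default designs: 80 single-dispenser
sessions of 6001 frames and 36 two-dispenser sessions of 9001 frames,
plus a 5 × 10-session sweep; the complete acceptance recomputation takes
on the order of ten seconds on one CPU, so no further scaling-down was
needed.
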