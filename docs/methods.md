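# Methods

This note documents the models, algorithms, numerical choices and
limitations behind `figana`, in the order data flows through the package.

## Reference geometry

The main shape is an irregular convex hexagon spanning the unit box.  The
published description of this item type fixes only the *topology* of the
figure — six corners, five internal lines forming a simple path, a
trapezium rotating about its own pivot, a broken circle adjacent to two
corners — so the concrete coordinates here are the package's reference
geometry, not a reproduction of any particular drawing.  Internal lines are
realized as hexagon diagonals visiting all six vertices; "corner *k*" always
means position *k* along that path.  Form presets A–D select four different
diagonal paths (internal forms) and four trapezium attachment edges
(external forms); only form A has any empirical pedigree, B–D are supplied
for completeness.  The hexagon is deliberately asymmetric so that all
16 rotation × reflection orientations render distinctly; this is what makes
the incidental space exactly 8 × 2 × 8 × 6 = 768.

Orientation is an element of the dihedral group of order 16, stored as
(`main_state` 1–8, `flipped`).  State *k* means a counterclockwise rotation
of 45·(k−1)° applied after an optional x-axis flip of the template.  With
this convention rotation is modular addition, x-reflection maps state *s* to
−s (mod 8), y-reflection to 4−s, and reflect∘reflect = identity holds
exactly by construction rather than by floating-point accident.

## Rules and pathways

Radicals act on disjoint parts of the figure (main-shape orientation,
trapezium state, line set, dot corner), so simultaneous radicals commute;
the fixed application order (reflection/rotation → trapezium → subtraction →
dot movement) exists only to make generation deterministic.  The same
disjointness makes the two solution pathways commute, which `solve_item`
nevertheless verifies on every call by computing D both ways.

Dot movement needs one genuinely open decision: the traversal direction.
The published description says the dot moves "in a particular direction"
without defining it.  Here a stem's direction is chosen deterministically:
+1 (toward path corner 6) when the summed movement fits, otherwise −1.
Because both pathway movements share the direction, D is the dot moved
`m_B + m_C` edges, and pathway agreement is exact.  When the summed movement
exceeds 3 and A's corner cannot host it, the dot is relocated to the nearest
of corners 5–6 (the broken-circle corners) that can — corner 6 hosts any
movement up to the full five edges, so relocation never fails.

Random subtraction (`subtract="R"`) resolves, per isomorph, to a seeded draw
of two *distinct* lines; equal lines would make B = C and leave the second
pathway infeasible.

## Distractor construction

Per-rule solutions are represented by their *effects*: a dihedral group
element for the main shape, a step count for the trapezium, a removed-line
set, a final dot corner.  Distinct effects on disjoint parts give distinct
option figures by construction, which is why the eight-option distinctness
invariant holds without search.  Auto-generated alternatives are near
misses: rotation offsets ±45°/±90° from the key, adjacent dot corners,
line sets sharing one line with the correct pair.  These magnitudes are the
package's choice — the source material prescribes none — made to keep
distractors plausible rather than trivially discardable.

Open design points resolved here:

* **3 × 3 elimination** (two-rule items): among the four both-incorrect
  combinations, the one most similar to the key (smallest summed effect
  distance, seeded tie-break) is dropped.
* **Position-9 replacement**: the key is replaced by the nearest single-rule
  swap not already present, falling back to an eliminated combination; in
  designs with neither (one- and three-rule items) a fresh alternative
  outside the design is drawn for one rule.
* **Extra rule of the 4 × 2 design**: drawn (seeded) from the general rules
  absent from the stem, keeping the reflection/rotation exclusion; its
  correct solution is "no change".  Suppressing it is allowed but warned
  about, since some single rules cannot supply seven distinct alternatives
  (a dot rule has only five other corners).

The default key position is drawn from 1–8.  Position 9 ("no answer is
correct") is honored when requested but flagged with a warning, since keying
the verbal option on difficult items is associated with reliability
problems; no stronger generation constraint can be derived, so a warning is
the honest implementation.

## Conditional maximum likelihood

For person *v* with raw score *r* on item set *S*, the Rasch conditional
likelihood of a response pattern is exp(−Σ x_i β_i)/γ_r(ε), with
ε_i = exp(−β_i) and γ_r the elementary symmetric function of order *r*.
ESFs are computed by the summation recursion; first- and second-order
derivative ESFs (one and two items removed) are recomputed by the same
recursion rather than by polynomial deflation, which is numerically unsafe
when some ε exceed 1.  The per-pattern difficulty vector is mean-shifted
before exponentiation (the conditional likelihood is shift-invariant), which
keeps every ESF well inside double range for any plausible difficulty
spread; at the 23-item scale full recomputation costs ~1 ms per Newton step.

Maximization is Newton–Raphson with analytic gradient (observed minus
conditionally expected scores) and Hessian (−Σ_r n_r Cov(x | r)), with step
halving, convergence at gradient ∞-norm < 1e−8, and a 200-iteration cap.
Item 1 anchors the scale during iteration; estimates are mean-centered
afterwards, and the covariance of the centered estimates follows by the
delta method.  Sum-to-zero versus reference-item conventions are
interconvertible; mean-centering is reported because difficulty plots are
conventionally drawn that way.  Missing responses are handled pairwise:
persons are grouped by missing pattern and each pattern contributes its own
ESF terms.  Persons with extreme raw scores (0 or maximum on their observed
items) carry no conditional information and are excluded and counted.
"I don't know" responses, when present in imported data, should be scored
incorrect before import; the fitters treat only NaN as missing.

The LLTM substitutes β = Qα; gradient and Hessian follow by the chain rule
(Qᵀg, QᵀHQ) and `beta_hat` is exactly Qα.  α is identified only when no
nonzero combination of Q's columns is constant across items — the
conditional likelihood sees difficulty *contrasts* only — so the model
refuses rank-deficient or constant-spanning Q matrices up front.

Test conventions: Andersen's LR uses a raw-score median split by default
with ties to the lower group (deterministic), df = (groups−1)(items−1).
The Wald test compares mean-centered subgroup estimates,
z = (β̂₁−β̂₂)/√(se₁²+se₂²).  The deviance comparison uses
df = (items−1) − p.  Cronbach's α uses complete rows and ddof = 1 variances.

## Simulator and study conditions

`simulate_responses` draws θ ~ N(0, 1) by default and Bernoulli responses
with probability logistic(θ − β), with ability and response substreams
spawned from one seed.  `PUBLISHED_RULE_DIFFICULTIES` ships the empirical
nine-rule basic-parameter estimates (traditional LLTM, conditional ML) from
a 23-item calibration study of this item type, as a realistic default α for
demonstrations; they are sample estimates, not ground truth.  The 23-item
demonstration bank mirrors that study's scale: nine single-rule items (one
per specific rule), seven two-rule, four three-rule and three four-rule
items, fixed so the implied Q matrix has full column rank.

Problem sizes used by the test suite are chosen to make the Monte Carlo
statements sharp at desk scale: 2000 persons × 100 replications for
basic-parameter recovery (each α within 3 SEs of truth in ≥95% of
replications), 300 persons × 500 replications for the Andersen type-I rate
(nominal 0.05, accepted band 0.03–0.08), difficulties in [−1.5, 1.5] for the
homogeneous simulations so that no subgroup item margin degenerates.

What the simulator does *not* emulate: guessing on multiple-choice options
(a Rasch process, not 3PL — real eight-option data show a guessing floor),
response times, position effects, practice effects, person misfit, or
"I don't know" usage.  Passing recovery tests therefore shows the
*estimators* are correct under the stated model, not that real
administrations follow it; on empirical data the Rasch–LLTM difficulty
correlation is typically far below the ~0.99 seen here, reflecting model
misfit rather than estimator error.

## Rendering

Matplotlib/Agg, fixed figure geometry and metadata, so exports are
byte-stable and idempotent.  Mode A reproduces the documented layout (stem
row, 4 × 2 option grid, verbal options beneath); modes B (single-column
options) and C (two-panel) are this package's variants — the original
layouts are not described anywhere reproducible.  German and Spanish verbal
strings are natural translations chosen here.  The answer key is a UTF-8
CSV with header `item_id, correct_position, rules_used` (semicolon-joined
general rules), positions in reading order.

## Known limitations

* Forms B–D and plot modes B–C are topology-preserving inventions; visual
  parity with any earlier implementation is out of scope.
* The warning-based capacity guarantee under a `constrict` restriction uses
  the product of active domain sizes; blocks guarantee coverage of the
  constricted part but repetition across blocks of the unconstricted parts
  is possible earlier than the bound.
* No marginal-ML or Bayesian estimation, no 2PL/3PL, no random-effects LLTM;
  reliability beyond Cronbach's α (e.g. GLB) and dimensionality analysis are
  out of scope.
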