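# figana

Rule-based automatic generation of **figural analogy items** (A:B::C:D with
geometric figures), together with the psychometric machinery to evaluate
them: Rasch and LLTM calibration by conditional maximum likelihood, model
tests, and a Rasch response simulator.

## Who this is for

Psychometricians and cognitive-assessment researchers who need renewable
banks of figural analogy items — e.g. for online testing, where item
exposure forces frequent renewal — and who want each item's difficulty to be
*predictable from its construction rules* rather than calibrated after the
fact.

## The item model

The basic figure is an irregular hexagon (the *main shape*) with five
internal line segments forming a path over its six corners, a dot sitting on
one corner, a trapezium attached outside one edge, and a broken-circle
glyph.  An analogy stem transforms figure A into B and into C by the same
rules with different arguments; the correct D must be reachable along both
pathways (A:B::C:D and A:C::B:D).

Five **general rules** (the item's radicals) are available, specialized into
nine **specific rules**:

| general rule        | specific variants                                   |
|---------------------|-----------------------------------------------------|
| main-shape rotation | short cw (90°/45°), short ccw, long cw (180°/135°)  |
| main-shape reflection | x-axis to B, y-axis to C                          |
| trapezium rotation  | short cw, short ccw, long cw                        |
| line subtraction    | one internal line per pathway                       |
| dot movement        | 1–5 edges along the internal path (sum ≤ 5)         |

Reflection and main-shape rotation are mutually exclusive (their composition
is confusable with another reflection), so at most **four radicals** act at
once.  *Incidentals* — the initial positions of A's parts — span
8 × 2 × 8 × 6 = **768** configurations; items sharing radicals and differing
only in incidentals are *isomorphs*.

The eight response options follow a **Solutions Combination Design (SCD)**:
per rule, one correct and several alternative solutions are crossed
(4 × 2, 3 × 3, 2³ or 2⁴ for 1–4 rules, with eliminations leaving exactly 8
options), the all-correct combination being the unique key.  Verbal options
"no answer is correct" (keyable as position 9) and "I don't know" complete
the item.

## The measurement models

Responses follow the Rasch model, P(correct) = logistic(θ_v − β_i).
Difficulties are estimated by **conditional maximum likelihood** (CML):
conditioning on raw scores removes the person parameters via elementary
symmetric functions.  The **LLTM** decomposes each difficulty into basic
parameters of the rules,

  β_i = Σ_j ω_ij α_j,

with ω the binary item × rule Q matrix.  Provided tests: Andersen's
conditional likelihood-ratio test (df = (groups−1)(items−1)), per-item Wald
tests across subgroups, the Rasch-vs-LLTM deviance test
(df = (items−1) − p), and Cronbach's α.

## Worked example

```python
import numpy as np
from figana import (RuleSet, build_items, fit_rasch_cml, fit_lltm_cml,
                    compare_deviance, andersen_lr, cronbach_alpha)
from figana.response_simulator import (demo_bank, qmatrix_from_bank,
                                       simulate_responses, SimConfig,
                                       PUBLISHED_RULE_DIFFICULTIES)

# two isomorphs of a two-rule item model
bank = build_items(RuleSet(main_rot=(90, 45), subtract=(1, 4)),
                   n_isomorphs=2, seed=42)
item = bank[0]
print(item.solution)
# FigureState(main_state=2, flipped=False, trap_state=4, dot_corner=4,
#             present_lines=frozenset({2, 3, 5}))
print(item.correct_position, item.rules_used)
# 8 ('main_rotation', 'subtraction')

# calibrate a simulated 23-item administration
b23 = demo_bank(seed=3)
q9 = qmatrix_from_bank(b23, rule_set_size=9)
beta = q9.weights @ PUBLISHED_RULE_DIFFICULTIES
resp = simulate_responses(beta, SimConfig(n_persons=2000, seed=11))
rasch = fit_rasch_cml(resp)
lltm = fit_lltm_cml(resp, q9)
print(lltm.summary())
```

```
Linear logistic test model (conditional maximum likelihood)
  items: 23   basic parameters: 9
  conditional log-likelihood: -17829.3448   iterations: 4
                     alpha      se        z       p
main_rot_short_cw   0.8630  0.0353  24.4164  0.0000
main_rot_short_ccw  1.6171  0.0396  40.8769  0.0000
main_rot_long_cw    1.2908  0.0382  33.8192  0.0000
trap_rot_short_cw   0.3464  0.0334  10.3567  0.0000
trap_rot_short_ccw -0.2712  0.0353  -7.6918  0.0000
trap_rot_long_cw    0.0628  0.0336   1.8671  0.0619
reflection          1.1836  0.0340  34.7910  0.0000
subtraction         0.6426  0.0285  22.5236  0.0000
dot_movement        0.3499  0.0284  12.3358  0.0000
```

Each `alpha` is the estimated difficulty contribution of one specific rule;
the simulation was generated from the shipped empirical estimates, and every
recovered value lies within a few standard errors of its generating value.
Continuing,

```python
print(round(cronbach_alpha(resp), 3))            # 0.788
print(andersen_lr(resp))                         # statistic=23.17, df=22, p=0.39
print(compare_deviance(rasch, lltm))             # statistic=15.12, df=13, p=0.30
print(np.corrcoef(rasch.beta, lltm.beta_hat_centered)[0, 1])  # 0.998
```

The Andersen test does not reject Rasch homogeneity, the deviance test shows
the nine-rule LLTM loses nothing relative to the Rasch model on data that
truly follow the LLTM, and the predicted difficulties correlate 0.998 with
the Rasch estimates — on real administrations the correlation is lower
because the linear rule decomposition is only an approximation.

## Command line

```bash
figana generate --main-rot 90,45 --subtract R --isomorphs 4 --seed 1 --out bank.json
figana render   --bank bank.json --mode A --language E --out items/
figana simulate --bank bank.json --persons 300 --seed 2 --out data/
figana calibrate --responses data/responses.csv --out fit.json
```

`render` writes one PNG per item per language plus `answer_key.csv` (item
id, correct position in reading order, general rules used).  `calibrate`
fits the Rasch model by default; add `--model lltm --qmatrix q.csv` to fit
an LLTM — that requires a bank whose items use *varied* rule sets (one
isomorph family shares a single Q row and cannot identify basic
parameters).

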