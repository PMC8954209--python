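# vftriage

Multi-attribute prioritization of ICU-admission candidates from
vague-fuzzy expert assessments.

## The problem

When intensive-care capacity is scarce, an admission team must order the
candidate patients by priority against several clinical criteria. Each
judgment — how reliable a colleague is, how important a criterion is, how a
patient stands on a criterion — is inherently uncertain. `vftriage`
represents every judgment as a **vague fuzzy number** ã = (t, 1−f): an
interval on [0, 1] whose lower bound t is the evidence *for* (truth
membership), whose upper bound 1−f encodes the evidence *against*
(false-membership f), and whose width 1 − t − f is the assessor's declared
indeterminacy. Consistency requires t + f ≤ 1. This is Atanassov's
intuitionistic formulation with μ = t and v = f.

Three geometric aggregation operators fuse sequences of vague numbers
ã₁…ãₙ with a weight vector summing to one:

- **IFWG** (weighted geometric): (∏ t_j^{ω_j}, ∏ (1−f_j)^{ω_j}), weights
  applied positionally;
- **IFOWG** (ordered weighted geometric): the values are first sorted by
  decreasing score, then position weights w are applied — input order is
  irrelevant;
- **IFHG** (hybrid geometric): each value is first re-weighted to
  ã̇_j = ã_j^{n ω_j} using importance weights ω, then sorted and combined
  with ordered weights w; with uniform ω it reduces exactly to IFOWG.

Ordered weights come from the **normal-distribution method**: position j of
n gets weight ∝ exp(−(j−μₙ)²/2σₙ²) with μₙ = (1+n)/2 and population σₙ,
softening the influence of extreme opinions. Defuzzification uses the
**score** S(ã) = t − f, with the **accuracy** t + f as tie-break.

The pipeline runs four stages:

1. **Expert weights** — the assessments each expert *receives* from peers
   are fused with IFOWG; the scores of the fused values are normalized to a
   weight vector ω.
2. **Criteria weights** — per criterion, the experts' importance
   assessments are fused with IFHG (importance = ω), scored, normalized.
3. **Collective matrix** — per (criterion, patient) cell, the experts'
   patient assessments are fused with IFHG (importance = ω).
4. **Ranking** — per patient, the collective column is fused across
   criteria with IFWG under the criteria weights; patients are ordered by
   decreasing score. The admission decision itself stays with the clinical
   team.

## Worked example

The package ships a five-expert, five-criterion, five-patient case study
with its published weight vectors:

```sh
triage demo
```

prints (abridged):

```
=== Expert weighting ===
aggregates: E1=(0.56, 0.73)  E2=(0.70, 0.86)  E3=(0.60, 0.90)  E4=(0.84, 0.98)  E5=(0.73, 0.88)
weights (fixed): E1=0.12  E2=0.19  E3=0.16  E4=0.30  E5=0.23
=== Criteria weighting ===
weights (fixed): C1=0.21  C2=0.39  C3=0.09  C4=0.16  C5=0.15
=== Collective matrix (criteria x patients) ===
                  P1              P2              P3              P4              P5
C1    (0.444, 0.679)  (0.685, 0.852)  (0.402, 0.848)  (0.611, 0.709)  (0.767, 0.871)
...
=== Patient aggregates and scores ===
aggregates: P1=(0.536, 0.766)  P2=(0.553, 0.789)  P3=(0.515, 0.845)  P4=(0.580, 0.839)  P5=(0.608, 0.832)
scores:     P1=0.302  P2=0.342  P3=0.361  P4=0.419  P5=0.441
=== Ranking (highest priority first) ===
P5 > P4 > P3 > P2 > P1
```

Expert E4 receives the strongest peer aggregate (0.84, 0.98) and therefore
the largest weight (0.30); criterion C2 dominates the criteria weights
(0.39); patient P5's aggregate (0.608, 0.832) has the highest score
(0.441), so P5 is the highest-priority admission candidate, followed by
P4, P3, P2, P1.

The same from Python:

```python
from vftriage import load_case_study, run_triage

result = run_triage(load_case_study(), use_fixed_weights=True)
print(result.ranking)        # ('P5', 'P4', 'P3', 'P2', 'P1')
print(result.scores[-1])     # 0.4405... (patient P5)
```

Other CLI commands: `triage run <problem.json|dir>` for your own problems
(JSON document or CSV bundle), `triage generate` for seeded random
problems, and `triage weights <problem> --block experts|criteria` to
inspect a single weighting block. Weight vectors are re-derived from the
raw assessments by default; `--use-fixed-weights` switches to the fixed
vectors stored in the problem file, and `--shift-negative-scores` opts in
to shift-normalization when aggregate scores are not all positive.

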