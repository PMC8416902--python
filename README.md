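# koaprog

Subtype and stage inference for knee osteoarthritis (KOA) from
cross-sectional biomarker data.

## The problem

KOA is phenotypically and temporally heterogeneous. Clustering knees by
biomarker similarity ("subtypes-only") tends to group knees of similar
*severity* rather than true phenotype; regressing a single severity axis
("stages-only") assumes every knee follows one common progression pattern.
`koaprog` implements a subtypes-progression model that infers both at once
from a single cross-sectional visit: each disease subtype is characterized
by its own ordering of *z-score events*, and each knee is placed at a
discrete stage along its subtype's ordering.

## The model

Each biomarker measurement is expressed as a z-score against a healthy
control group, sign-flipped where the raw measure decreases with disease
(joint space width, cartilage thickness) so that z always rises with
severity. A **z-score event** is a biomarker crossing a threshold
z ∈ {1, 2, 3, 5}; events observed in fewer than 10 subjects are dropped,
and a biomarker whose largest retained event is z = 1, 2, 3, 5 is assigned
a maximum z-score of 2, 3, 5, 7 respectively. The S retained events define
stages 0..S.

For subtype *c* with event ordering σ_c, the expected value of biomarker
*i* at stage *k* interpolates linearly between the knots (0, 0),
(p₁, z₁), ..., (p_m, z_m), (S, max-z), where p_j is the position of event
(i, z_j) in σ_c. Observations are Gaussian around the stage's expected
value (σ = 1 on the z scale), stages carry a uniform prior, and the data
likelihood is the mixture

  P(x) = Σ_c f_c · (1/(S+1)) Σ_{k=0..S} Π_i N(x_i ; μ_i(k; σ_c), σ_i²)

maximized over orderings σ_c and fractions f_c by greedy coordinate ascent
over event positions inside an EM loop, growing hierarchically from one
subtype. The number of subtypes is chosen by the cross-validation
information criterion, CVIC = −2 · log P(X|M), summed over 10 held-out
folds. Posterior uncertainty in each ordering comes from
Metropolis–Hastings sampling over permutations, summarized as an
event × position frequency matrix (positional variance diagram). Each
subject receives posteriors over subtypes and stages; a subject is
*strongly assigned* when its top subtype probability is ≥ 1.5× each other
subtype's.

A three-way evaluation compares this subtypes-progression model with a
subtypes-only baseline (diagonal Gaussian mixture on radiographically
diseased knees, severity grade ≥ 2) and a stages-only baseline (the same
progression model restricted to one sequence), via logistic regression on
the task of separating grade 0/1 from grade ≥ 2 knees (predictors: stage,
subtype, injury, gender, age, BMI) with likelihood-ratio statistics.

Because the motivating cohort (678 knees from the Osteoarthritis
Initiative) is access-restricted, the package ships a synthetic cohort
generator that emulates its statistical structure — 13 biomarkers carrying
32 z-score events, subtype fractions, uniform stages, unit-variance
Gaussian noise, a Kellgren–Lawrence-like grade thresholded on the true
stage, and demographics — so every stage of the pipeline is testable with
known ground truth.

## Worked example

```python
import numpy as np
from koaprog import (CohortConfig, SubtypeProgressionModel, assign,
                     generate_patient_cohort, random_subtype_specs,
                     sequence_kendall_tau)
from koaprog.events import Event, EventSet

# five biomarkers, events at z=1 and z=2 each -> S = 10 stages
es = EventSet(
    events=tuple(Event(f"bm{i}", z) for i in range(5) for z in (1.0, 2.0)),
    max_z={f"bm{i}": 3.0 for i in range(5)},
)

# two ground-truth subtypes progressing biomarkers in opposite orders
specs = random_subtype_specs(es, (0.5, 0.5), seed=1, reversed_pair=True)
cohort = generate_patient_cohort(
    CohortConfig(event_set=es, subtypes=specs, n_subjects=600, seed=1)
)

model = SubtypeProgressionModel(
    event_set=es, n_subtypes=2, n_starts=6, split_starts=4, random_state=0
).fit(cohort.z_values)

print("fractions:", np.round(model.fractions_, 3))
taus = [[sequence_kendall_tau(np.asarray(s.sequence.order), np.asarray(f.order))
         for f in model.sequences_] for s in specs]
print("tau matrix:", np.round(taus, 2))
post = assign(cohort.z_values, model)
print("first subject: subtype", post[0].ml_subtype, "stage", post[0].ml_stage,
      "(truth:", cohort.truth_subtype[0], cohort.truth_stage[0], ")")
```

Output:

```
fractions: [0.491 0.509]
tau matrix: [[ 1.   -0.78]
 [-0.78  1.  ]]
first subject: subtype 0 stage 7 (truth: 0 5 )
```

The fitted mixing fractions sit within sampling error of the generating
50/50 split. The Kendall-tau matrix between true and fitted orderings is
1.0 on the diagonal — each fitted sequence reproduces its generating
sequence exactly — and −0.78 off the diagonal, the separation between the
two reversed subtypes. The first subject is correctly assigned to
subtype 0; its stage estimate (7 of 10) sits two stages from the truth
(5), typical of staging noise at unit z-score noise.

The same pipeline is scriptable from the shell:

```bash
koaprog simulate --seed 1 --out sim/
koaprog preprocess --cohort sim/cohort.csv --controls sim/controls.csv \
    --defs sim/biomarker_defs.csv --out prep/
koaprog fit --zscores prep/zscores.csv --eventset prep/event_set.json \
    --c 3 --seed 0 --out model.json
koaprog select --zscores prep/zscores.csv --eventset prep/event_set.json \
    --c-range 1:3 --seed 0 --out cvic.json
koaprog assign --zscores prep/zscores.csv --model model.json --out assigned.csv
```

## Limitations

The synthetic generator emulates the *statistical* structure of a KOA
cohort, not its clinical content; see `docs/methods.md` for the model's
assumptions, parameter choices, and known limitations.
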