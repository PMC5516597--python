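# recallnet

Structural-connectome correlates of episodic memory: a tested, reusable
implementation of a population-level brain-network analysis pipeline, for
researchers relating a behavioural phenotype (here: the number of pictures a
subject freely recalls) to DTI-based structural connectivity in large
cohorts.

Each subject contributes a symmetric 82 × 82 matrix of inter-regional
connection probabilities (68 Desikan–Killiany cortical + 14 subcortical
regions). The pipeline:

1. **filters spurious connections** at the population level — edge *(i, j)*
   is kept iff mean(C<sub>ij</sub>) + 2·sd(C<sub>ij</sub>) ≥ 0.01 across
   subjects;
2. **computes weighted graph metrics** — network cost
   κ = Σ<sub>i&lt;j</sub> w<sub>ij</sub> / (R(R−1)/2) (equal to the mean
   nodal degree k<sub>i</sub> = Σ<sub>j≠i</sub> w<sub>ij</sub>/(R−1)),
   Onnela weighted clustering, characteristic path length on 1/w lengths
   (optionally normalized by degree-preserving rewired surrogates), global
   and nodal efficiency, betweenness centrality, and **cost-integrated**
   versions of the global metrics (binarize at each density of a grid from
   1/(R(R−1)/2) up to the largest density common to all subjects, then
   average);
3. **runs a hierarchical FDR cascade** — Spearman associations between
   residualized recall (age, gender regressed out) and residualized network
   measures (age, gender, intracranial volume regressed out), tested global
   → nodal → edge with Benjamini–Hochberg control within each level and
   each level gated on rejection below;
4. **runs the network-based statistic (NBS)** — per-edge OLS t-statistics
   with covariates, suprathreshold components at T = 2.5 (one-sided
   p ≈ .0063 at df ≈ 660), FWE p-values from a permutation null of maximal
   component size;
5. **quantifies joint edge effects** with a robust bisquare (Tukey,
   c = 4.685) multiple regression R²; and
6. **checks grey-matter volumetry** as a control analysis.

Because no subject-level cohort is publicly deposited, the package ships a
**calibrated synthetic cohort generator** (`recallnet.synthetic`): a
lognormal connectome template, a latent memory trait driving valence-split
binomial recall counts, a Gaussian-copula global effect calibrated by
Monte-Carlo root-finding so that Spearman(cost, recall) hits a requested
value, planted effect edges calibrated in closed form to a requested joint
R², and covariate confounding — so every stage is testable end-to-end.

## Worked example

```bash
# simulate a cohort with a planted global effect and 22 effect edges
cat > sim.yaml <<EOF
n: 664
rho_global: 0.102
n_effect_edges: 22
edge_r2_target: 0.078
EOF
recallnet simulate --config sim.yaml --seed 1 --out fixture/

# run the full pipeline
recallnet run --matrices fixture/matrices --atlas fixture/atlas.tsv \
              --cohort fixture/cohort.csv --seed 1 --out report/
```

The same analysis from Python:

```python
import numpy as np
from recallnet import (SyntheticConfig, simulate_cohort, population_edge_mask,
                       residualize, robust_r2, spearman_assoc)

cohort = simulate_cohort(SyntheticConfig(seed=1, rho_global=0.102,
                                         n_effect_edges=22, edge_r2_target=0.078))
mask = population_edge_mask(cohort.stack)           # floor = 0.01
arr = cohort.stack.weight_array() * mask.retained
iu, ju = np.triu_indices(82, 1)
cost = arr[:, iu, ju].sum(1) / 3321                 # network cost per subject

co = cohort.cohort
recall = residualize(co.column("recall_total"),
                     np.column_stack([co.column("age"), co.column("gender")]))
cost_r = residualize(cost, np.column_stack([co.column("age"),
                                            co.column("gender"), co.column("icv")]))
print(spearman_assoc(cost_r, recall, B=2000, seed=1))

edges = np.array(cohort.truth["effect_edges"])
X = cohort.stack.weight_array()[:, edges[:, 0], edges[:, 1]]
print(robust_r2(recall, X).r_squared)
```

prints (seed 1):

```
AssociationResult(r=0.09118993580554996, p=0.018759728638054966, ci_low=0.012850886513030001, ci_high=0.1654893574300979, n=664, B=2000, seed=1)
0.06072293709236909
```

i.e. this particular replicate recovers a cost–recall rank correlation of
.091 with a bootstrap CI of [.01, .17] (the planted value is .102; the
sampling sd at n = 664 is ≈ .04), and the 22 planted edges jointly explain
6.1% of recall variance in this draw (planted in-sample target 7.8%,
replicate sd ≈ 2 points).

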