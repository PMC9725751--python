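# lineagestat

Statistics of selection on cellular lineage trees.

Growing microbial and mammalian cell populations are heterogeneous: even in
a constant environment, sister lineages accumulate different numbers of
divisions, and faster-dividing lineages are over-represented among the
survivors. `lineagestat` quantifies this intra-population selection from
single-cell lineage data — full genealogies from time-lapse microcolonies,
or isolated lineages from mother-machine microfluidics — for
microbiologists, quantitative cell biologists and evolutionary modellers
who want model-free measures of how phenotypic heterogeneity feeds into
population growth.

## The statistics at its core

Each lineage σ (the history of one cell alive at the end of a window of
length τ) carries a division count D(σ) and optional traits X(σ). Two
weights are placed on the same lineages: the chronological probability
P_cl(σ) = 2^(−D)/N₀ (a random downward walk through the tree — the
population *before* selection) and the retrospective probability
P_rs(σ) = 1/N_τ (uniform over survivors — *after* selection). With the
binned trait distributions Q_cl(x), Q_rs(x) the package computes:

- the **fitness landscape** h(x) = τΛ + ln(Q_rs(x)/Q_cl(x)), where
  Λ = (1/τ)ln(N_τ/N₀); for the division count, h̃(d) = d·ln2 exactly;
- **selection strengths** S_KL1[X] = D_KL(Q_cl‖Q_rs) = τΛ − ⟨h⟩_cl,
  S_KL2[X] = D_KL(Q_rs‖Q_cl) = ⟨h⟩_rs − τΛ, and the Jeffreys divergence
  S_JF = S_KL1 + S_KL2, plus the relative strength
  S_rel[X] = S_KL1[X]/S_KL1[D] ∈ [0, 1] with a permutation null;
- the **cumulant expansion of growth**: K_X(ξ) = ln⟨e^{ξh}⟩_cl satisfies
  K(1) = τΛ = Σ_n κ_n/n!, so W_n = (1/τΛ)Σ_{k≤n}κ_k/k! measures how much of
  population growth the first n fitness cumulants (mean, variance,
  skewness, …) explain;
- the **perturbation response**: removing newborn cells with probability
  1 − 2^(−ε) gives Λ(ε) = K_D(1−ε)/τ, with initial relative slope
  −(1 + S_KL2[D]/τΛ) — heterogeneous populations grow faster (S_KL1) but
  also lose more growth under perturbation (S_KL2);
- a gamma branching-process **simulator** (optionally with mother–daughter
  generation-time correlations) and a lineage **bootstrap** for
  uncertainties, so every estimator is validated without external data.

## Worked example

The smallest interesting genealogy: one founder; the first daughter never
divides again, the second divides once more, so the three lineages have
D = (1, 2, 2) over a 1-hour window.

```python
from lineagestat import CellRecord, LineageSelectionModel, parse_cell_table

cells = [
    CellRecord("A",  None, 0.0, 0.3, "divided"),
    CellRecord("A1", "A",  0.3, 1.0, "alive_at_end"),
    CellRecord("B",  "A",  0.3, 0.6, "divided"),
    CellRecord("B1", "B",  0.6, 1.0, "alive_at_end"),
    CellRecord("B2", "B",  0.6, 1.0, "alive_at_end"),
]
ensemble = parse_cell_table(cells, t_start=0.0, t_end=1.0)
results = LineageSelectionModel(ensemble).fit(n_boot=1000, seed=0)
print(results.summary())
```

```
Lineage selection analysis
============================================================
trait: D                      mode: tree
lineages: 3                   window tau: 1 h
N0: 1.0                       Ntau: 3
------------------------------------------------------------
tau*Lambda           1.098612 nats
Lambda               1.098612 /h
<h>_cl               1.039721 nats
<h>_rs               1.155245 nats
Var[h]_cl            0.120113 nats^2
Var[h]_rs            0.106767 nats^2
S_KL1                0.058892 nats   (gain fraction 0.0536)
S_KL2                0.056633 nats
S_JF                 0.115525 nats
S_rel                1.000000
W1                   0.946395
W2                   1.001061
skewness(h)_cl      -0.000000
cumulant series converged at n=20: True
------------------------------------------------------------
statistic              point   boot mean     boot sd
tau_lambda           1.09861     1.12896     0.20366
mean_fitness_cl      1.03972     1.09399     0.22015
mean_fitness_rs      1.15525     1.16403     0.18807
S_KL1                0.05889     0.03497     0.02635
S_KL2                0.05663     0.03506     0.02596
W1                   0.94639     0.96600     0.02504
W2                   1.00106     0.99918     0.00274
```

Reading the numbers: the population tripled (τΛ = ln 3 ≈ 1.0986 nats).
Without selection the mean lineage fitness would be ⟨h⟩_cl = 1.5 ln 2 ≈
1.0397 nats; the missing 0.0589 nats is S_KL1[D], i.e. division-count
heterogeneity contributes 5.4% of the population's growth (W₁ = 0.946 of
growth comes from the mean alone, and adding the fitness variance brings
W₂ ≈ 1). S_KL2 = 0.0566 nats predicts the perturbation response: removing
newborns at strength ε shrinks growth with initial relative slope
−(1 + 0.0566/1.0986) ≈ −1.05, steeper than the −1 a homogeneous population
would show — confirmed by `results.perturbed_growth(0.1)` → 0.9836 /h.
The bootstrap columns are lineage-resampling means and SDs (3 lineages, so
the intervals are wide).

The same analysis runs from the shell on cell tables, Newick trees or
mother-machine lineage tables:

```sh
lineagestat analyze colony_cells.tsv --format cells --t-start 0 --t-end 5 \
    --trait rpos_mcherry --boot 20000 --outdir report/
lineagestat simulate --shape 2 --eps-max 0.2 --runs 1000 --seed 1
```

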