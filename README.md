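# netpercolate

Percolation-based *virtual lesion* analysis of weighted brain networks,
with functional-data statistics over the full range of network densities.

## The problem

How robust is a functional brain network to the loss of its regions, and
how does that robustness change across development?  Virtual-lesion
studies answer this by removing nodes from a subject's connectome — at
random, or targeted by a centrality metric — and watching the network
disintegrate.  On finite graphs the classical "giant component vanishes"
percolation criterion is useless (the largest component only reaches
size 0 when every node is gone), so disintegration is instead defined
through the **second-largest connected component**: the *percolation
point* is the fraction of nodes removed at which S2 first peaks.

Graph metrics also depend strongly on the density at which a weighted
connectome is thresholded, and no single threshold is privileged.
`netpercolate` therefore computes the percolation point at every density
of a dense proportional-threshold grid and treats the result as a
*function* of density, analysed with function-on-scalar regression (FoSR)
— no threshold needs to be pre-selected, and no mass-univariate
correction is needed.

## What the package does

1. **Connectivity** — from node-level oscillatory recordings, Slepian
   multitaper cross-spectra on a narrowband grid (default 0.5–100 Hz in
   0.5 Hz steps, ±2 Hz smoothing), the weighted phase lag index per bin

       wPLI_ij(f) = |E[Im S_ij(f)]| / E[|Im S_ij(f)|],

   and L2 aggregation across bins into one weighted connectome per
   subject.  Precomputed adjacency matrices can be supplied instead.
2. **Attacks** — proportional thresholding over a density grid (top
   fraction of edges by weight, production default 0.25 %–100 % in
   0.25 % steps), node removal at random or by descending betweenness /
   eigenvector centrality (computed once on the intact thresholded
   graph, ties randomized), 100 iterations per density, and the mean
   percolation point per density.  Removal-frequency maps record which
   nodes fall before network failure across subjects.
3. **Functional preprocessing** — terminal-spike outlier removal
   (z > 2 on the lowest-density value), domain trimming to the
   informative low-density range, order-4 B-spline smoothing with knots
   at the grid points (`n_densities + 2` basis functions) and a
   GCV-selected second-derivative penalty, used to flag subjects whose
   functions fit poorly (SSR z > 2).  Modeling uses the *unsmoothed*
   trimmed functions.
4. **FoSR** — `y_i(d) = Σ_j x_ij β_j(d) + ε_i(d)` with covariates age,
   sex, handedness, and mean Euclidean node distance; each β_j(d) is
   expanded in 5 cubic B-splines with a first-order difference penalty
   (P-splines) and a shared REML-selected smoothing weight.  Inference:
   an overall constancy F test, per-covariate drop-one F tests, adjusted
   and functional R², semi-partial correlations, case-bootstrap pointwise
   95 % bands, and a three-condition significance rule reporting the
   density ranges over which a covariate matters.

A synthetic-data module generates phase-coupled oscillator recordings
with known wPLI structure and cohorts of modular weighted graphs whose
inter-module connectivity shifts from redundant (young) to
hub-concentrated (old) as a continuous age covariate increases — so every
stage is testable without access to protected neuroimaging data.

## Worked example

```python
import numpy as np
import netpercolate as npk

spec = npk.SyntheticCohortSpec(n_subjects=60, master_seed=7)
cohort = npk.generate_cohort(spec)
rec, conn = cohort[0]
print(rec.id, round(rec.age_years, 1), rec.sex, round(rec.mean_node_distance, 1))
# sub-000 13.1 female 102.4

cfg = npk.AttackConfig(strategy="betweenness",
                       densities=np.arange(1, 31) / 100, n_iter=25, seed=rec.seed)
res = npk.run_attacks(conn, cfg)
print(round(res.mean_percolation[4], 3))   # percolation point at 5% density
# 0.141
```

The subject above is 13.1 years old; removing nodes in betweenness order
from the 5 %-density graph disintegrates the network after ~14 % of nodes
are removed.  Younger subjects in the same cohort tolerate more removals
(their inter-module bridges are redundant); the full pipeline quantifies
this as a negative age coefficient function at low densities:

```python
cfg = npk.PipelineConfig(mode="synthetic", output_dir="out", seed=7,
                         cohort={"n_subjects": 60},
                         strategies=["random", "betweenness"],
                         n_iter=25, n_boot=200)
manifest = npk.run_pipeline(cfg)
print(manifest["strategies"]["betweenness"]["significant"]["age"])
# {'significant': True, 'direction': -1.0, 'ranges': [(0.01, 0.01), (0.03, 0.06)]}
```

i.e. age is negatively and significantly associated with the percolation
point over low densities: older synthetic subjects' networks fail
earlier under betweenness-targeted attack.

The same pipeline runs from the shell:

```bash
netpercolate simulate --out cohort/ --seed 7
netpercolate attack --adjacency cohort/ --strategy betweenness --out perc.tsv
netpercolate run --config cfg.yaml
```

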