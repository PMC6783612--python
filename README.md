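# connectokit

Graph-theoretical analysis of FA-weighted structural brain connectomes
for two-group (patient vs control) studies, with a synthetic-cohort
generator that makes every stage testable without imaging data.

## The problem

Diffusion-MRI tractography yields, per subject, a symmetric N×N
connectivity matrix whose nodes are parcellated brain regions and
whose edge weights are the mean fractional anisotropy (FA ∈ [0, 1)) of
the connecting white-matter streamlines. Comparing such networks
between a patient group and matched controls — for example in motor
neuron disease, where tract degeneration is expected around the motor
cortex — raises three coupled questions this package answers:

1. **Where and how much is the network altered?** Per-subject graph
   metrics and their group comparison:
   - node degree `k_i` (count of nonzero edges at node *i*),
   - global efficiency `Eglob = mean over pairs of 1/d(i,j)` with
     `d(i,j)` the shortest path length using edge length `1/w`,
   - local efficiency `Eloc_i` (Eglob of the subgraph induced by
     *i*'s neighbors),
   - betweenness centrality `BC_i = Σ_{s≠t≠i} σ_st(i)/σ_st`
     (unordered pairs, unnormalized).
2. **Is the damage hub-centered?** Hubs are nodes whose group-mean
   degree exceeds the across-node mean by more than one SD. The hub
   disruption index κ of a subject is the OLS slope of
   `(subject profile − control mean profile)` against the control mean
   profile across nodes: κ = 0 means no reorganization, κ < 0 means
   high-degree regions are preferentially hit.
3. **Is there a coherent impaired subnetwork?** Network-based
   statistics (NBS): threshold edge-wise two-sample statistics at a
   primary threshold, extract connected components of the
   supra-threshold graph, and assign each component a family-wise
   error corrected p-value from the permutation distribution of the
   maximal component extent under group-label shuffling. Per-subject
   FA sums over a significant component quantify individual tract
   integrity.

The statistical layer mirrors standard practice for a 164-region
parcellation: unpaired rank-sum tests per node reported at a
Bonferroni threshold 0.05/164 ≈ 0.0003 and an exploratory threshold
1/164 < 0.006; Spearman correlations of network metrics with clinical
scores (ALSFRS-R, and the disease progression rate
`(48 − ALSFRS-R)/duration`), judged at 0.0125 (global) and 0.004
(nodal); Kruskal–Wallis and chi-squared (no Yates correction) for
demographics.

Because real cohorts of this kind are rarely shareable, the package
ships a first-class synthetic generator
(`SimulationConfig`/`generate_cohort`) that plants controlled,
recoverable effects: a low-FA subnetwork, degree deficits at chosen
nodes, a target hub-disruption slope, and a target Spearman coupling
between a nodal metric and the progression rate. See
`docs/methods.md` for the generative model and its limitations.

## Worked example

```python
import connectokit as ck

study = ck.ConnectomeGroupStudy.from_synthetic(
    ck.SimulationConfig(n_nodes=60, n_patients=12, n_controls=13,
                        degree_sd=12.0,
                        planted_component=[(0, j) for j in range(1, 6)],
                        fa_effect=0.2, degree_deficit_nodes=[20, 21],
                        edge_removal_prob=0.15, clinical_rho=-0.5, seed=17),
    nbs_config=ck.NBSConfig(n_permutations=1000, seed=17))
print(study.fit().summary())
```

prints (abridged):

```
Connectome group analysis
============================================================
config hash 8bad384c8f51bc27, seed 17, 12 patients vs 13 controls, 60 nodes (weighted mode)

Global metrics (patients vs controls, rank-sum):
  eglob        0.3113 vs 0.3120   p = 0.3992
  mean_degree  40.2222 vs 40.5513   p = 0.0178
  ...
Nodal degree: 3 node(s) below the Bonferroni threshold, 3 below the exploratory threshold
Hubs (patient): 7 of 60 nodes (threshold 49.84)
Hubs (control): 7 of 60 nodes (threshold 50.18)
kappa-degree: patients -0.012, controls -0.002, p = 0.1827

NBS: 3 supra-threshold component(s), 1000 permutations
  * 6 nodes / 5 edges, p_fwer = 0.0010
  ...
Clinical correlations (patients):
    degree[node 20] ~ progression_rate: rho = -0.5674, p = 0.0543
```

Reading it: the two planted deficit nodes (20, 21) plus the planted
component's hub node drive the nodal flags; NBS recovers the planted
5-edge star as its significant component (p_fwer = 0.001); the
hub-disruption indices stay near 0 (no hub reorganization was
planted); and the planted negative coupling between node-20 degree
and the progression rate appears with the right sign and magnitude.

The same analysis runs from files
(`ConnectomeGroupStudy.from_files(manifest, matrix_dir, labels)`,
matrices as headerless delimited text) or from the command line:

```bash
connectokit simulate --seed 17 --out cohort/
connectokit run --config analysis.yaml --out report/
```

`StudyResults.save(outdir)` writes `report.json` plus CSV tables;
reports are byte-identical across runs with the same seed.

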