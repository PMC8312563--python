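# wmnet

Graph-theoretic analysis of white-matter structural connectomes, built
for case-control studies of the kind used to characterize sudden
sensorineural hearing loss (SSNHL): per-subject streamline-count
matrices over the 90-region AAL parcellation are binarized by a
fiber-number threshold, summarized by small-world and centrality
metrics, screened for hub regions, and compared between groups with
covariate-adjusted statistics. A synthetic cohort generator with
planted, tunable group effects makes every stage testable without
diffusion MRI data.

## What it computes

For each subject an undirected, unweighted network is built over the
atlas nodes: an edge exists between regions *i* and *j* iff at least FN
streamlines connect them (FN swept over 1–5, analysis anchored at
FN = 3). From each network:

- **Global parameters** — clustering coefficient Cp, characteristic
  path length Lp (mean over finite distances; the disconnected-pair
  fraction is reported alongside), local efficiency locE, global
  efficiency gE, and the normalized parameters
  γ = Cp/⟨Cp<sub>null</sub>⟩, λ = Lp/⟨Lp<sub>null</sub>⟩, σ = γ/λ,
  where the null ensemble is m = 100 Maslov–Sneppen degree-preserving
  rewirings. σ > 1 indicates small-world organization.
- **Nodal centralities** — degree Di, nodal efficiency Ei, and
  unnormalized Brandes betweenness Bi, plus per-node clustering and
  path length.
- **Hubs** — one point each for: top 20% Di, top 20% Bi, bottom 20%
  nodal clustering, bottom 20% nodal path length; score ≥ 2 ⇒ hub.
  Group hub tables come from subject-averaged nodal metrics and are
  compared as shared / group-specific sets.
- **Group statistics** — demographics (t-test / χ²), general linear
  model per parameter with age, gender and education regressed out
  (positive t ⇔ controls > patients), Bonferroni correction over the
  90-node family for nodal tests, and partial Pearson correlations of
  flagged parameters with PTA, THI and duration within the patient
  group.

## Worked example

```python
from wmnet import (CohortConfig, generate_cohort, threshold_network,
                   build_ensemble, normalized_metrics)

matrices, table = generate_cohort(CohortConfig(n_controls=1, n_patients=1, seed=3))
net = threshold_network(matrices["HC001"], 3)
nm = normalized_metrics(net, build_ensemble(net, m=100, seed=0))
print(f"gamma={nm.gamma:.3f} lambda={nm.lam:.3f} sigma={nm.sigma:.3f}")
```

prints

```
gamma=4.134 lambda=1.082 sigma=3.821
```

— the control network is strongly clustered relative to degree-matched
random graphs (γ ≈ 4.1) while keeping near-random path lengths
(λ ≈ 1.1), i.e. a small-world topology (σ ≈ 3.8 > 1). The
`examples/` directory has one short script per capability (simulation,
construction, metrics, small-worldness, hubs, group statistics, full
pipeline), each printing the numbers it computes with a note on what
they mean.

The same flow is available from the shell:

```bash
wmnet simulate --seed 1 --n-controls 8 --n-patients 8 --out data/
wmnet analyze  --config run.yaml --seed 1
wmnet report   --out wmnet_run/
```

`analyze` writes tab-separated report tables (global parameters per
threshold, adjusted group comparisons, Bonferroni-corrected nodal
tests, hub tables, clinical correlations) and a JSON run summary, all
reproducible from the seed.

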