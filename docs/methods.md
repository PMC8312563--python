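# Methods

## Scope and model

wmnet analyzes binary, undirected anatomical networks over a fixed
parcellation (the packaged node table is the 90-region AAL ordering,
with a coarse functional class per region). The pipeline starts at the
streamline-count matrix: tractography, registration and atlas warping
are upstream of this package and out of scope. Counts are assumed
symmetric with a zero diagonal; asymmetric inputs are rejected rather
than symmetrized, since a correctly aggregated unordered-pair tally is
symmetric by construction.

An edge exists where the streamline count reaches the fiber-number
threshold FN (default 3, swept over 1–5 to show threshold robustness).
Isolated nodes are retained; every metric handles them.

## Metric conventions

- **Clustering**: Watts–Strogatz nodal coefficient
  c_i = 2·e_i / (k_i(k_i−1)); nodes with degree < 2 get c_i = 0. Cp is
  the unweighted mean over *all* nodes (not triangle density).
- **Path length**: distances are BFS hop counts. L_i is the mean finite
  distance from node i to the nodes it can reach (undefined for an
  isolated node); Lp is the mean over all finite off-diagonal ordered
  pairs, and the fraction of unreachable pairs is always reported next
  to it. This finite-pairs convention keeps Lp defined on disconnected
  graphs without inventing a pseudo-distance; the efficiency metrics
  are unaffected by the choice because unreachable pairs contribute
  exactly 0 there.
- **Efficiency**: gE is the mean of 1/d over ordered pairs (1/∞ = 0);
  E_i the mean over partners of one node; locE averages, over all
  nodes, the global efficiency of the subgraph induced on each node's
  neighbors (degree < 2 contributes 0).
- **Betweenness**: Brandes' algorithm on the unweighted graph, each
  unordered source–target pair counted once, endpoints excluded, left
  unnormalized — normalization cancels in the rank-based hub criteria
  and only rescales group contrasts.

Shortest paths run through scipy's sparse-graph routines and
betweenness through networkx; clustering and the efficiencies are
vectorized in-package. All of them are checked in the test suite
against brute-force enumeration oracles (Floyd–Warshall, triangle
counting, exhaustive geodesic enumeration) on small random graphs.

## Null models and small-worldness

γ, λ and σ = γ/λ normalize Cp and Lp by the mean over an ensemble of
degree-preserving surrogates. A surrogate is produced by attempting
`swap_factor · |E|` double-edge swaps (a,b),(c,d) → (a,d),(c,b); swaps
creating self-loops or duplicate edges are skipped, so the degree
sequence is preserved exactly. Defaults m = 100 members and
swap_factor = 10 follow common connectome-toolbox practice and are
configurable. Connectedness is deliberately *not* enforced during
rewiring — rejecting disconnected surrogates would bias the null;
members whose Lp is undefined are excluded from the λ denominator and
counted. Member seeds are `seed + index` for auditability.

## Hub identification

k = ceil(0.2·n) nodes are selected per criterion (high Di, high Bi, low
nodal clustering, low nodal path length); ties at the selection
boundary break toward the lower node index, and an undefined nodal path
length ranks last (an isolated node can never be "shortest-path
central"). Scores 0–4; hub ⇔ score ≥ 2. Group hub tables are computed
from subject-averaged nodal metrics — the criteria are defined on nodal
metrics, so averaging metrics (rather than building a group-mean
network) keeps the object being ranked well-defined; undefined nodal
path lengths are excluded from the per-node average with their count
reported.

## Group statistics

Global and nodal parameters are compared with OLS:
`metric ~ 1 + group + age + gender + education`, the group indicator
coding controls as 1 so a positive t means controls exceed patients.
Covariate columns that are constant across subjects are dropped (the
model then reduces exactly to the pooled t-test); genuinely collinear
designs raise an error naming the columns. Global parameters are
reported with raw p-values; nodal tests are Bonferroni-corrected over
the node family separately per centrality type (the most literal
reading of a "90-node" correction). Clinical associations use partial
Pearson correlations — both variables residualized on the same
covariates, p from t = r·sqrt(df/(1−r²)) with df = n − 2 − #covariates
— reported uncorrected, restricted to parameters flagged by the group
comparison, and computed within the patient group only (THI and
duration do not exist for controls). Residuals that are numerically
zero (relative tolerance 1e-10) leave the correlation flagged
undefined.

## Synthetic cohort generator

The generator defines the study conditions for all simulation-based
tests. Defaults mirror the emulated cohort: 91 controls vs 145
patients; age ≈ 38.5 ± 12 y truncated to [18, 80]; gender Bernoulli
0.5 (coded 1 = male); education ≈ 13 ± 3.5 y; PTA 12.1 ± 4.0 dB HL
(controls) vs 78.2 ± 28.6 (patients); THI 45.6 ± 24.9 clipped to
[0, 100]; duration 8.4 ± 4.2 days.

Topology: a ring lattice over 90 nodes with mean degree 6, each edge
rewired with probability 0.1 (Watts–Strogatz), is the shared base —
the minimal generator with tunable Cp/Lp that reproduces small-world
organization in both groups. Six planted hub regions (PreCG.L/R,
PCUN.L/R, PUT.L/R in the AAL ordering) each receive 8 extra random
edges, giving them the high-degree / high-betweenness / low-clustering
/ short-path profile the hub criteria select.

Each subject's network perturbs the base in order: (1) extra rewiring
(patients only, probability 0.3 per edge) — the randomization shift
that lowers clustering and γ; (2) uniform edge deletion (patients only,
fraction 0.2) — global hypoconnectivity. Rewiring alone *shortens*
paths (it creates shortcuts), so an edge-loss component is required to
reproduce the empirically observed pattern of increased Lp with
decreased Cp, locE and gE; the default 0.2 was calibrated once on the
generator itself (6 seeds × 12 + 12 subjects: minimum patient–control
ΔLp = +0.09 with ΔCp = −0.21, ΔgE = −0.02, ΔlocE = −0.32); (3) nodal
degree deficits (patients only; default fraction 0.3 of incident edges
at IFGoperc.R, PUT.L, PUT.R, rounded down, uniformly chosen); (4)
independent edge flips at rate 0.01 per region pair — per-subject
noise.

Streamline counts are Poisson: mean 20 on true edges, 0.05 on
non-edges, chosen so the FN = 3 rule is a high-fidelity edge detector
(P(Pois(20) < 3) ≈ 5e-7 misses; P(Pois(0.05) ≥ 3) ≈ 2e-5 false edges).
With a spurious mean of 0.5 the false-edge rate at FN = 3 would be the
Poisson tail 1.44e-2 — more than 1% — which is why the default spurious
mean is an order of magnitude smaller.

Clinical coupling is rank-based: normal scores of each patient's
realized Lp (a monotone surrogate for λ at fixed null mean) are mixed
with independent noise to hit a target correlation (+0.18 for THI,
−0.18 for duration, the magnitudes of the emulated associations), then
the independently drawn THI/duration marginals are assigned by latent
rank. This guarantees the marginal distributions exactly and a monotone
association of the configured strength without distributional
commitments.

All randomness flows from one integer seed: a master generator creates
the base topology and covariates and derives one child seed (< 2³¹) per
subject, so cohorts are byte-identical across runs and insertion of new
subjects does not perturb existing ones.

### What the generator does and does not emulate

It reproduces the *structure* the analysis assumes — two groups, a
small-world substrate, group differences of the observed sign pattern,
degree deficits at designated regions, covariates and weakly coupled
clinical variables. It does not emulate spatial embedding, hemispheric
symmetry, distance-dependent connection probability, realistic degree
distributions of tractography networks, or scanner/tractography error
structure. Passing tests therefore certify the correctness and
calibration of the analysis machinery under controlled conditions, not
the empirical findings of any real cohort; real-cohort effect sizes
cannot be inferred from the planted ones.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to make their statistical
claims sharp while staying desk-scale: the threshold-sweep
small-worldness check runs 20 + 20 subjects with m = 100 nulls per
subject per threshold; type-I calibration uses 5000 replicates (GLM and
χ²) and 500 ninety-node families for the Bonferroni FWER; the power
check for the planted global effects uses 50 cohorts at the full
91/145 size; oracle equivalence uses 200 random graphs with n ≤ 8,
where exhaustive enumeration is exact. Degenerate inputs follow the
conventions above (degree < 2, isolated nodes, edgeless graphs,
zero-variance residuals); selection ties in hub scoring are broken
deterministically by node index; Bonferroni caps at 1 exactly.

## Known limitations

- Binary networks only; weighted variants (FA- or count-weighted) are
  out of scope, as are modularity, rich-club and prognosis modeling.
- The finite-pairs Lp convention makes Lp non-comparable across
  subjects whose disconnected-pair fractions differ substantially; the
  fraction is reported so such cases are visible (at FN ≤ 5 with the
  default generator they are rare).
- γ is undefined for triangle-free networks (0/0) and noisy when null
  clustering is near zero, as in very sparse graphs.
- Group hub tables from subject-averaged metrics are one of two
  defensible aggregations (the other: hubs of a group-representative
  network); results can differ near the selection boundary.
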