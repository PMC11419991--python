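# Methods

`fcarchetypes` implements a pipeline for discovering *archetypal*
resting-state functional-connectivity (RSFC) profiles and probing
*degenerate* brain-behavior coding — the situation where structurally
different connectivity configurations are associated with the same
behavioral outcome. This note documents the models, the tunable
parameters, the synthetic-data generator, and the numerical and design
choices a user should know about.

## Pipeline model

The unit of analysis is one functional connectome per (subject, run): an
N x N symmetric matrix of Fisher-z transformed Pearson correlations
between parcel time series, with zero diagonal. Runs are stacked as
separate observations, so within-subject variability across runs is part
of the data rather than averaged away.

1. **Feature reduction.** Each connectome's strict lower triangle is
   flattened to an edge vector of length N(N-1)/2 (column-major within
   the lower triangle). PCA is run on the centered edge vectors (no
   per-feature standardization: edges are already on a common z scale).
   The number of components is chosen by Horn-style parallel analysis:
   observed correlation-matrix eigenvalues are compared rank by rank with
   the 95th percentile of eigenvalues from shape-matched standard-normal
   null datasets; counting stops at the first rank that fails, so the
   retained set is a leading prefix. Retained scores are z-scored.
2. **SOM clustering.** A self-organizing map with a (Dx x Dy) rectangular
   neuron grid is trained online: every observation moves its best
   matching unit (BMU) and, through a Gaussian neighborhood on the grid,
   that unit's neighbors, with learning rate and neighborhood radius
   decaying linearly over epochs. Each observation's label is its BMU;
   the neuron's grid coordinate (x, y) becomes the observation's
   archetype coordinate.
3. **Stability tuning.** Candidate grid sizes are screened at a fixed
   epoch count; the surviving grids get a full epoch sweep. Every
   (dims, epochs) cell trains `n_repeats` independently seeded SOMs and
   records the mean Adjusted Rand Index (ARI) and Adjusted Mutual
   Information (AMI, arithmetic-mean normalization) over all run pairs.
   The most stable cell wins, with ties broken toward fewer epochs and a
   smaller grid (parsimony, to avoid over-trained configurations).
4. **Consensus clustering.** An ensemble of independently seeded SOMs is
   trained at the selected configuration. The consensus matrix M holds
   the fraction of runs in which each observation pair co-clusters;
   average-linkage hierarchical clustering of 1 - M, cut at k = Dx * Dy
   clusters, gives the final partition. The ensemble run with the highest
   mean(ARI, AMI) against that partition is the *representative run*; its
   grid coordinates are the archetype coordinates used downstream. This
   is also how the SOM's label/axis exchangeability is resolved: consensus
   works purely on co-assignment (label-free), and only the single
   representative run's coordinates are ever interpreted.
5. **Consistency null.** The mean number of distinct archetypes per
   subject is compared with a Monte-Carlo null in which every run gets an
   i.i.d. uniform label in 1..k. The null mean converges to the occupancy
   expectation k(1 - (1 - 1/k)^R); the one-sided empirical p-value is the
   fraction of null simulations at or below the observed mean. An option
   to draw null labels from the empirical cluster frequencies (for
   unbalanced archetypes) is available by passing observed frequencies;
   the default is uniform.
6. **Association battery.** Behavior scores are Box-Cox transformed
   (lambda by maximum likelihood) and min-max rescaled to [1, 100], then
   regressed on the archetype coordinates as categorical factors X, Y and
   their interaction X:Y. Two arms form a small multiverse: a two-way
   ANOVA with Type-II sums of squares (Type III optional) treating every
   connectome as an observation, and a linear mixed model with a random
   intercept per subject guarding against the pseudo-replication that
   arises when a per-subject trait is replicated across runs. Post-hoc
   Welch t-tests compare grid cells that differ in exactly one coordinate
   (4 of the 6 pairs on a 2x2 grid; cross-diagonal pairs enter through
   the interaction term), with Benjamini-Hochberg and Bonferroni
   corrections within each behavior's family. Across behaviors, a tier
   map marks raw p < 0.001, FDR survival, and Bonferroni survival over
   the whole behaviors x terms family.
7. **Degeneracy readout.** Each behavior is classified by its most
   significant term surviving the chosen tier (X-coded / Y-coded /
   interaction-coded / uncoded). For interaction-coded behaviors, a
   *degenerate pair* is two archetypes whose cell means are statistically
   indistinguishable (Welch p >= 0.05, uncorrected) while their mean
   connectomes are at least as distant as the median pairwise archetype
   distance. By default only pairs sharing an *elevated* outcome (pooled
   mean above the behavior's grand mean) are reported, because the
   phenomenon of interest is different connectivity profiles producing
   the same high score; `direction="both"` also reports low-outcome
   pairs.

## Key parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| `n_sim`, `percentile` | 10,000, 95 | Parallel-analysis null datasets and retention percentile. Tests and the acceptance script use smaller `n_sim` (100-1,000); the null thresholds depend only on the data shape and can be precomputed and reused. |
| `dims_list` | 2x2 .. 10x10 | Grids screened in tuning step 1. |
| `epochs_list` | 40..260 step 20 | Epoch sweep in tuning step 2 (screen at 100). |
| `n_repeats` | 200 | SOM repetitions per tuning cell (desk-scale runs use 4-20). |
| `n_consensus_runs` | 100 | Ensemble size for consensus (desk-scale 10-30). |
| `alpha` | 0.5 -> 0.01 | SOM learning rate, linear decay over epochs. |
| `sigma` | max(Dx,Dy)/2 -> 0.5 | Gaussian neighborhood radius in grid units, linear decay. |
| Box-Cox lambda bound | [-5, 5] | The unconstrained MLE diverges when a score's location is much larger than its spread; bounding the exponent keeps the transform stable without affecting any practically relevant shape. |

SOM specifics are fully pinned down for reproducibility: rectangular
topology, Euclidean grid distance, Gaussian neighborhood, online updates
in seeded shuffled order, one epoch = one full pass, BMU ties to the
lowest neuron index, neuron index i at coordinate
x = 1 + (i-1) mod Dx, y = 1 + floor((i-1)/Dx). Weight initialization
samples data rows without replacement (a linear initialization along the
top two principal axes is available). Any residual run-to-run variability
is absorbed by the consensus layer. Training is bit-reproducible under a
fixed seed in single-threaded execution.

## Synthetic data generator

The generator emulates the structure of a multi-run RSFC study without
any real time series: S subjects x R runs of N-node Fisher-z connectomes
(defaults 200 x 4 x 90). The first ceil(N/3) nodes form an "anterior"
block whose within-block connectivity increases with the X grid level,
the next ceil(N/3) a "posterior" block driven by Y, the rest are
background; templates share a constant baseline (0.1 z) and each grid
step adds `block_effect` (default 0.75 z) to its block. Observations are
templates plus i.i.d. symmetric Gaussian edge noise (default 0.5 z, so
effect/noise = 1.5). Each subject draws a modal archetype uniformly; each
run keeps it with probability `run_consistency` (default 0.8) and
otherwise resamples uniformly over all cells, so the empirical match rate
converges to rho + (1-rho)/K and rho = 0 reduces to i.i.d. uniform
assignment. Behaviors are generated per subject from the modal cell —
constant across runs, like a trait — as baseline + d*sigma*g + noise,
where g indicates the last X level (X-coded), last Y level (Y-coded), the
XOR of the two (interaction-coded, the degenerate pattern: cells (2,1)
and (1,2) share the high outcome), or nothing (null).

What the generator does *not* emulate: BOLD time series, autocorrelated
or spatially structured noise, head motion and preprocessing artifacts,
unequal archetype prevalence, real psychometric distributions, or
behavior that varies across runs. Passing tests therefore demonstrate
that the pipeline recovers planted block-structured archetypes and
coding patterns under i.i.d. Gaussian edge noise — a necessary
correctness property — not that it would recover archetypes of the same
strength in empirical data, where nuisance structure can mimic or mask
cluster structure.

## Numerical choices and degenerate inputs

- Correlations with |r| >= 1 raise unless clipping to +/-(1 - 1e-7) is
  enabled (arctanh diverges; real data never reaches the boundary).
- Parallel analysis warns when features outnumber observations (rank
  deficiency); trailing eigenvalues are exact zeros and can never exceed
  a positive null threshold. Retention is additionally capped at the
  numerical rank of the PCA spectrum (eigenvalues above 1e-9 of the
  total), and features whose variance is below 1e-13 of the maximum are
  dropped as numerically constant — both guards matter only for
  noiseless synthetic input. If parallel analysis retains nothing, one
  component is kept with a warning.
- ARI/AMI degenerate conventions: two single-cluster partitions compare
  as 1; single- vs multi-cluster as 0 (the chance-corrected forms are
  0/0 there).
- Average-linkage cut uses the k-cluster criterion, not a height
  threshold. If ties make the cut produce fewer than k groups, the
  achieved number is returned with a warning.
- The mixed model is fit by REML; Wald chi-square tests per fixed-effect
  term. When scores are exactly constant within subject (a trait
  replicated across runs) the random intercept fits every subject
  perfectly, the residual variance collapses, and fixed effects are
  unidentified — the fit is flagged degenerate rather than reporting
  misleading p-values, and the battery's subject-level mode (one row per
  subject at the modal coordinate) is the appropriate arm.
- A 2x2 SOM partitions even structureless data somewhat reproducibly
  (two runs quantize the *same* cloud), so "instability" on noise means
  ARI well below the clustered-data ceiling, not ARI near zero; near-zero
  ARI is only expected between independent random labelings.

## Test and acceptance problem sizes

The packaged test suite and `scripts/acceptance.py` run the full
procedure at desk scale: 200 subjects x 4 runs x 90 nodes for recovery
checks (parallel-analysis null at `n_sim` = 100 with thresholds
precomputed once per data shape), 400 x 300 with `n_sim` = 1,000 for the
rank-14 retention check, 100,000 simulations for the occupancy-formula
check, 1,000 null datasets for ANOVA type-I calibration, and 100 seeds
for XOR power. Tuning in the acceptance script sweeps 2x2 and 3x3 grids
at 60 and 100 epochs with 4 repeats and a 20-run consensus ensemble.
These sizes are the package's own evaluation choices; the full-fidelity
defaults above remain available through the configuration.

## Known limitations

- Equivalence with other SOM implementations is procedural, not bitwise:
  neighborhood shape, decay schedules, and initialization differ across
  toolboxes, and no published default set is uniquely canonical.
- The degenerate-pair connectivity criterion (median pairwise archetype
  distance) is an operational definition; the underlying phenomenon is
  qualitative.
- Type-II sums of squares are the default for unbalanced designs; Type
  III is available but interacts with factor coding in the usual ways.
- The observation-level ANOVA arm deliberately mirrors a design in which
  connectomes are replicated observations; its p-values are
  anti-conservative under within-subject correlation, which is exactly
  why the mixed-model / subject-level arms are always reported alongside.
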