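# fcarchetypes

Discovery of **archetypal functional-connectivity profiles** with
stability-tuned self-organizing maps (SOMs) and consensus clustering, and
detection of **degenerate brain-behavior coding** via grid-coordinate
association analysis.

## The problem

Resting-state functional connectivity (RSFC) predicts behavior only
inconsistently. One explanation is *degeneracy*: structurally different
connectivity configurations can support the same behavioral outcome, so
any single linear brain-behavior map is underdetermined. This package
implements a pipeline for surfacing that structure in multi-run
connectome datasets:

1. connectomes (Fisher-z correlation matrices, one per subject and run)
   are vectorized and reduced by PCA, with the component count chosen by
   Monte-Carlo **parallel analysis** (eigenvalues must beat the 95th
   percentile of shape-matched noise, rank by rank);
2. the reduced profiles are clustered by a **2-D SOM**: each observation
   is assigned to the neuron (archetype) with the nearest weight vector,
   and every archetype carries a grid coordinate (X, Y);
3. grid size and training epochs are selected by a two-step **stability
   search** maximizing the pairwise Adjusted Rand Index / Adjusted Mutual
   Information (ARI/AMI) of repeated clusterings;
4. repeated SOM runs are aggregated by **consensus clustering** — the
   co-assignment probability matrix M is agglomerated with average
   linkage on 1 − M and cut at the grid's cluster count; the run closest
   to the consensus supplies the archetype coordinates;
5. within-subject assignment consistency is tested against a
   random-assignment **Monte-Carlo null** (mean unique archetypes per
   subject vs the occupancy expectation k(1 − (1 − 1/k)^R));
6. behaviors (Box-Cox normalized, rescaled to 1–100) are regressed on the
   grid coordinates: two-way **ANOVA** (Type-II SS) and a **linear mixed
   model** (random intercept per subject) for X, Y and X:Y, restricted
   post-hoc comparisons, FDR and Bonferroni corrections; behaviors whose
   dominant effect is the X:Y **interaction** are screened for
   *degenerate pairs* — archetypes with indistinguishable behavior but
   distant mean connectomes (the XOR pattern, where cells (X2,Y1) and
   (X1,Y2) share a high outcome through very different connectivity).

Real multi-run RSFC data of this kind is access-restricted, so the
package ships a first-class synthetic-data generator that plants a known
2-D archetype grid (an "anterior" node block driven by X, a "posterior"
block driven by Y), within-subject run consistency, and behaviors with
known coding — everything needed to validate the pipeline end to end
against ground truth.

## Worked example

```python
from fcarchetypes import (
    SynthConfig, simulate_dataset, simulate_behavior, reduce_dataset,
    ConsensusSOM, adjusted_rand_index, random_assignment_null,
    consistency_test, preprocess_behaviors, association_battery,
    summarize_archetypes, degeneracy_report,
)

cfg = SynthConfig(n_subjects=60, n_runs=4, n_nodes=30, seed=11)
cs, truth = simulate_dataset(cfg)

rf = reduce_dataset(cs, n_sim=100, seed=1)
model = ConsensusSOM(dims=(2, 2), epochs=25, n_runs=10, random_state=2)
model.fit(rf.scores)
print("components retained:", rf.n_components)
print("recovery ARI:", adjusted_rand_index(model.labels_, truth.labels_per_obs()))

null = random_assignment_null(60, 4, k=4, n_sims=5000, seed=3)
rep = consistency_test(model.representative_labels_, cs.subject_ids, null)
print(f"unique archetypes/subject: {rep.observed_mean:.3f} "
      f"(null {rep.null_mean:.3f}, p={rep.p_value:g})")

beh, _ = preprocess_behaviors(simulate_behavior(truth, effect_size=1.2, seed=4))
result = association_battery(beh, model.coords_, cs.subject_ids,
                             use_lme=False, level="subject")
report = degeneracy_report(result, summarize_archetypes(cs, model.coords_),
                           tier="fdr")
for name, entry in report["behaviors"].items():
    print(name, "->", entry["coding"],
          [p["cells"] for p in entry["degenerate_pairs"]])
```

Output:

```
components retained: 2
recovery ARI: 1.0
unique archetypes/subject: 1.600 (null 2.735, p=0)
discounting -> Y-coded []
fluid_intelligence -> X-coded []
loneliness -> interaction-coded [[[1, 2], [2, 1]]]
null_trait -> uncoded []
```

Two retained components match the two planted grid factors; the consensus
partition reproduces the planted archetypes exactly; subjects' runs are
far more consistent than the random-assignment null (mean 1.6 unique
archetypes vs 2.735); and the behavior battery recovers each planted
coding, including the degenerate pair — archetypes (1,2) and (2,1) share
high loneliness despite opposite connectivity profiles. (Which planted
factor appears as "X" is arbitrary: SOM axes are exchangeable.)

## Command line

```bash
fcarch simulate --config config.yaml      # write synthetic dataset
fcarch run      --config config.yaml      # full pipeline -> run_report.json
fcarch report   out/run_report.json       # summarize a report
```

`fcarch run` executes reduce → tune → consensus → nullcheck → associate →
degeneracy and writes a single deterministic JSON report (same config and
seed ⇒ byte-identical bytes). All randomness derives from one global
seed through named per-stage sub-seeds recorded in the report.

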