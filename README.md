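# psma — probabilistic surfaces of molecular activity

Build a 2D activity landscape from a molecular similarity matrix and use
it as a spatial binary classifier.

The pipeline:

1. **Similarity → distance.** A square similarity matrix (values in
   [0, 1], e.g. from a graph-matching similarity engine or Tanimoto
   fingerprint comparison) is transformed into a distance matrix.  The
   default is the convex transform
   `d = 1 − k·s / (1 + k − s)` with `k = 0.382`, which inflates
   distances among highly similar molecules; `1 − s`, `1/s − 1` and
   `−ln s` are also available.
2. **2D projection.** Four distance-preserving methods operate directly
   on the distance matrix: principal coordinates analysis (`pcooa`),
   Kruskal non-metric MDS (`kmds`), Sammon mapping (`sammon`) and t-SNE
   on precomputed distances (`tsne`).  The iterative methods start from
   the PCooA solution; Shepard r² and stress quantify distortion.
3. **Density + Bayes.** Per-class 2D Gaussian KDEs (Silverman
   bandwidths, pooled across classes) are combined with class priors
   into a posterior probability of activity at every (x, y) — a surface
   you can contour-plot or query as a classifier.
4. **Out-of-sample embedding.** The linear map `T = pinv(D) · C`
   reproduces the training coordinates exactly for full-rank `D` and
   places new molecules from their similarity rows to the training set.
5. **Validation.** Stratified train/test split, ROC/AUC and MCC.

A synthetic-data module generates cluster-structured sets whose latent
coordinates map back to similarities through the exact algebraic inverse
of the convex transform, so every stage is testable with known ground
truth and no external data.

## CLI

```sh
# make a synthetic data set (similarity.tsv + activity.tsv)
psma synth --preset unbalanced --seed 1 --out data/

# full protocol: split, project, fit, embed the test set, score, write
psma run --similarity data/similarity.tsv --activity data/activity.tsv \
         --method pcooa --seed 1 --out results/run1/

# compare all four projection methods on one shared split
psma compare --similarity data/similarity.tsv --activity data/activity.tsv

# classify molecules already placed in the reference plane
psma predict --model results/run1/model.json \
             --coordinates results/run1/coordinates.tsv

# embed + classify new molecules from similarity rows to the training set
psma embed --model results/run1/model.json --similarities queries.tsv

# export the posterior surface (grid TSV + JSON sidecar + contour PNG)
psma surface --model results/run1/model.json --grid 150 --out surf/
```

Input formats (tab/comma/semicolon delimited, auto-detected):

- similarity matrix: header row + index column of molecule ids, square
  numeric body in [0, 1];
- activity: `id, ki_nM` (positives are Ki ≤ 10 nM by default, set
  `--cutoff-nm`) or `id, label` with `1/0` or `active/inactive`;
- fingerprints: `id, bitstring` of `0`/`1` characters.

Exit codes: 0 ok, 2 validation/format error, 3 numerical failure.

## Library use

```python
import psma

data = psma.make_fixture("unbalanced", seed=1)
result = psma.run_pipeline(data.similarity, data.activity_table(),
                           psma.RunConfig(method="pcooa", split_seed=1))
print(result.report["auc"], result.report["mcc"])
```
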