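# emograph

Emotion recognition from multichannel physiological recordings: mutual-information
functional connectivity of EEG channels, weighted graph-theory features of the
resulting networks, fusion with windowed statistical features of peripheral
channels, genetic-algorithm wrapper feature selection, and classifier/CNN
evaluation under subject-dependent and subject-independent (leave-one-subject-out)
protocols.

## Pipeline

1. **Windowing** — trials are cut into 4 s windows with a 2 s step; each window
   inherits its trial's valence/arousal ratings (1–9), dichotomized at 4.5 into
   low/high.
2. **Peripheral features** — 12 time-domain statistics per peripheral channel per
   window (mean, variance, std, max, min, skewness, kurtosis, q25/q50/q75,
   zero-crossing rate, approximate entropy); 8 channels → 96 features.
3. **EEG connectivity** — pairwise mutual information (equal-width histogram
   plug-in, 8 bins, bits) between all electrode pairs → a complete weighted
   adjacency matrix per window. No thresholding or normalization is applied.
4. **Graph measures** — 5 global (characteristic path length, global efficiency,
   transitivity, modularity, density) + 4 node-level vectors (clustering
   coefficient, local efficiency, betweenness centrality, degree centrality =
   node strength); 14 electrodes → 61 features. Path-based measures traverse
   1/weight edge lengths; density is the literal sum of edge weights.
5. **Fusion + selection** — concatenation (peripheral block then graph block),
   optional GA wrapper selection with classifier accuracy on an inner
   stratified 85/15 split as fitness (defaults: 200 generations, population
   100, 10 parents, pool 4, 3 mutations per offspring, elitist).
6. **Evaluation** — SVM / random forest / gradient-boosted trees / 1-D CNN
   (three conv-pool blocks, Adam, binary cross-entropy, implemented in numpy);
   subject-dependent 85/15 splits or leave-one-subject-out, reported as mean ±
   std accuracy across subjects.

A fully seeded synthetic-data generator plants class-dependent EEG coupling and
class-dependent peripheral statistics so the whole pipeline is testable without
any external dataset. An adapter for per-subject array archives
(`data: trials × channels × samples`, `labels: trials × 4`) is included.

## CLI

```sh
emograph generate --spec gen.yaml --out data/ --seed 1      # synthetic recordings (HDF5)
emograph extract  --data data/ --out features.csv           # per-window feature table
emograph select   --features features.csv --out mask.json   # GA feature selection
emograph evaluate --features features.csv --protocol loocv \
                  --classifier cnn --out report.json --seed 0
emograph report   report.json                               # mean ± std table
```

`--config config.yaml` supplies a declarative `PipelineConfig` (window/step,
channel subset, MI bins, ApEn parameters, GA and CNN settings); CLI flags
override file values.

## Notes and conventions

- Moments are population (divide by N); kurtosis is excess; quantiles use
  linear interpolation. Constant signals yield 0 for skewness/kurtosis/ZCR/ApEn
  rather than NaN.
- ZCR is computed on the mean-centred signal; exact zeros inherit the previous
  nonzero sign.
- ApEn defaults: m = 2, r = 0.2 × std, Chebyshev distance, self-matches
  included.
- Degree centrality is node strength because a literal link count is constant
  on a complete weighted MI graph; betweenness is normalized to [0, 1].
- Modularity is the best weighted Newman Q found by deterministic greedy
  agglomeration plus single-node refinement.
- In the subject-dependent protocol, windows of one trial may appear on both
  sides of the 85/15 split (the protocol taken literally); this is optimistic
  on autocorrelated signals. `group_by_trial=True` keeps trials intact.
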