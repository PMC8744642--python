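# enrichopt

Enrichment-optimized linear ranking models for ligand-based virtual
screening, with the full evaluation harness around them: descriptor
preprocessing, screening-realistic train/validation/test splits, ROC/AUC
and enrichment-factor metrics, best-score consensus ranking, Y-scrambling,
active–decoy distance analysis, and a synthetic active/decoy benchmark
generator with planted, analytically tractable signal.

## Who this is for

Computational chemists who rank large compound libraries with cheap 1D/2D
descriptors and want the *model derivation itself* to optimize what virtual
screening is judged by — early recognition of actives — rather than a
regression or classification loss that only correlates with it.

## The method

Given `L` active and `O` inactive (or decoy) compounds described by `N`
z-scored molecular descriptors, an EOA model is a fixed-size linear ranking
rule

```
score(x) = Σᵢ wᵢ · xᵢ          (subset of n descriptors, no intercept)
```

scored against a ranked list by two terms:

- **primary score** — the number of actives within the first `L` places of
  the ranked list (an enrichment count, bounded by `L`);
- **secondary score** — a tie-breaker in `(0, 1]`. With the total rank
  displacement

  ```
  D = Σ_{active at rank r > L} (r − L)  +  Σ_{inactive at rank r ≤ L} (L + 1 − r)
  ```

  the secondary score is `2 / (1 + exp(D/τ))`: exactly 1 at perfect
  separation and strictly decreasing in `D` (default `τ = L`).

The total objective `primary + secondary` is optimized by Metropolis Monte
Carlo in the joint space of descriptor subsets and weights (swap one
descriptor, or perturb one weight), under a saw-tooth simulated-annealing
schedule: RT swept 1.00 → 0.01 in 0.01 steps, 400 MC steps per rung,
repeated in 40,000-step cycles (defaults; 1,000,000 steps total). Because
the secondary term never reaches 1 unless separation is perfect, putting
one more active into the top `L` always dominates any rearrangement below —
the search is enrichment-first by construction.

Performance is reported with the two standard screening metrics: AUC
(probability a random active outranks a random decoy, tie-corrected) and
the enrichment factor `EF_f = (a/A)/f`, with `a` the actives among the top
`⌈f·N⌉` compounds.

## Worked example

```bash
eoa simulate  --actives 50 --decoys 500 --descriptors 100 --seed 1 --out bench.csv
eoa preprocess --input bench.csv --out clean.csv --report-out filter.tsv
eoa train  --input clean.csv --n-desc 7 --steps 50000 --seed 1 --out model.json
eoa screen --model model.json --input clean.csv --ef 0.01 --ef 0.05 --out report.json
```

The simulated deck plants 5 informative descriptors (actives shifted by
2 SD) among 95 nuisance columns. Preprocessing removes 15 of them
(`{'correlated': 10, 'constant': 5}` in `filter.tsv` — exactly the planted
redundant and constant columns). Training reaches the objective

```
{'primary': 49, 'displacement': 5, 'secondary': 0.9500, 'total': 49.9500}
```

i.e. 49 of the 50 actives inside the top-50 window, the stray active only
5 positions deep. The screening report on the same table reads

```
L 50   top_L_count 49   top_L_percent 98   auc 0.9998   ef {0.01: 12.0, 0.05: 11.2}
```

`EF_1% = 12.0` means the top 1% of the ranked deck (6 compounds, all
active) holds 12× the active fraction of a random pick; the ceiling for
this deck is `1/f` at small fractions. The same calls are available as
library functions (`generate_benchmark`, `filter_descriptors`,
`zscore_normalize`, `optimize`, `evaluate_model`) — the CLI is a thin
wrapper and produces byte-identical artifacts for identical seeds.

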