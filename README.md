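# gpcrtracer

Integrated tracer-discovery analysis toolkit for GPCR ligand engagement:
balanced dataset construction from GPCR–ligand interaction tables,
fingerprint-based multiclass family classification, class-probability
promiscuity profiling, chemical-space embedding, NanoBRET competitive-screen
statistics, and prediction-vs-screen concordance — all exercisable end to end
on synthetic data, with no external downloads.

## Modules

| Module | What it does |
| --- | --- |
| `gpcrtracer.synthetic` | GLASS-like interaction tables with family-clustered chemistry (scaffold + substituent decoration), simulated BRET plates and saturation series |
| `gpcrtracer.dataset` | ingestion filtering (human/id/parseable SMILES), structure-level dedup per family, 700-compound family threshold, balanced 530-per-family selection, stratified 70/30 split |
| `gpcrtracer.fingerprints` | 758-position concatenated vector (167 MACCS keys + 79 E-State atom-type counts + 512 FP4-style substructure bits) and near-zero-variance feature filtering |
| `gpcrtracer.classifier` | random-forest family classifier with repeated stratified CV, features-per-split tuning, confusion matrix, per-family one-vs-rest metrics, randomized-label control |
| `gpcrtracer.promiscuity` | multi-family interaction calls from class probabilities at an inclusive ≥4% threshold |
| `gpcrtracer.chemspace` | UMAP embedding of the MACCS block (Jaccard metric) with neighbor sweep and silhouette reporting |
| `gpcrtracer.bret` | BRET ratios, fold responses (≥1.5 positivity call), signal/noise, screen summaries, one-site saturation fits |
| `gpcrtracer.concordance` | scaffold × family overlap between thresholded predictions and consolidated screen confirmations, with a probability-threshold sweep |

## CLI

Every stage is exposed as a `gpcrtracer` subcommand; `--seed` is required
wherever randomness is involved.

```bash
gpcrtracer simulate-data --n-families 4 --compounds-per-family 100 \
    --promiscuous-fraction 0.05 --seed 7 --output interactions.csv
gpcrtracer build-dataset --input interactions.csv --min-compounds 50 \
    --n-per-family 80 --train-fraction 0.7 --seed 7 --output split.csv
gpcrtracer fingerprint --input split.csv --fit-mask --output fp.csv
gpcrtracer train --input split.csv --folds 5 --repeats 10 --seed 7 \
    --model-out model.joblib
gpcrtracer evaluate --input split.csv --model model.joblib \
    --metrics-out metrics.json --confusion-out confusion.csv
gpcrtracer control --input split.csv --permute-labels --seed 7
gpcrtracer predict-profile --input scaffolds.csv --model model.joblib \
    --threshold 4 --output profiles.csv
gpcrtracer embed --input split.csv --n-neighbors 50 --seed 7 \
    --output umap.csv --plot umap.png
gpcrtracer screen-analyze --input plate.csv --threshold 1.5 \
    --concentrations 1000,100 --output screen.csv
gpcrtracer concordance --predictions pred.csv --confirmations conf.csv \
    --output concordance.json
```

## Notes

- The FP4-style block is computed from a vendored SMARTS functional-group
  pattern list (`src/gpcrtracer/data/fp4_patterns.smarts`) so the dialect is
  frozen with the package; positions past the last pattern are always zero.
- The near-zero-variance rule removes a feature iff it is constant, or its
  most-common/second-most-common frequency ratio exceeds 95/5 while its
  percent-unique is below 10%.
- The fold-response positivity threshold (≥1.5) and the promiscuity
  probability threshold (≥4%) are both inclusive.
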