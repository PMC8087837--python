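# colonygate

Range-gate classification of colonial phytoplankton from
imaging-flow-cytometry particle images.

Cyanobacterial blooms of *Microcystis* are dominated by colonial
morphospecies (*M. aeruginosa*, *M. ichthyoblabe*, *M. novacekii*,
*M. smithii*, *M. wesenbergii*) whose identification normally requires an
expert taxonomist at a light microscope.  Benchtop imaging flow cytometers
photograph every particle in a water sample and measure simple
morphological descriptors per particle, which makes a semi-automated
alternative possible: describe each taxon by a *filter set* — a
conjunction of inclusive `[min, max]` gates on particle properties — and
call a particle a member of the class when it passes every gate.  This
package implements that whole workflow for ecologists and cytometrists
who want to classify colonial taxa (or audit such a classification)
without proprietary instrument software:

* **Particle features** (`colonygate.particles`) — segmentation of one
  particle per brightfield frame and the ten properties used by the
  gates: Average Blue, Diameter (ABD), Edge gradient, Intensity, Length,
  Perimeter, Ratio red/blue, Ratio red/green, Roughness, and Sigma
  intensity.  The area-based diameter is `2·sqrt(A/π)` in µm; Length is
  the largest of 36 Feret (caliper) measurements over a half turn;
  Perimeter counts every exposed pixel edge including interior holes;
  Roughness is perimeter over convex-hull perimeter (exactly 1 for a
  filled convex rectangle).
* **Range-gate classifiers** (`colonygate.gates`) — per class, gates are
  fitted at the min/max of a randomly drawn training subset (25 or 50 of
  a 150-particle pool), then reduced by greedy backward elimination
  while the overall accuracy `(TN + TP)/total` stays above 0.75, and the
  "25" and "50" filters are narrowed into an *intersection* filter
  (highest min, lowest max per feature).  `RangeGateClassifier` exposes
  this as a scikit-learn estimator (`fit` / `predict` / `select`).
* **Validation metrics** (`colonygate.metrics`) — confusion matrices
  with precision and false discovery rate, balanced accuracy
  `(TPR + TNR)/2`, the Hellinger distance
  `HD = (1/√2)·sqrt(Σ_k (√(X_k/X) − √(T_k/T))²)` between training and
  test composition (0 for identical, 1 for disjoint), per-class SMAPE,
  Bray–Curtis dissimilarity and Kullback–Leibler divergence.
* **Synthetic colony generator** (`colonygate.synthetic`) — labelled
  brightfield frames (or feature tables) for seven classes: the five
  *Microcystis* morphospecies plus *Micractinium* (spiny colonies) and
  *Cryptomonas* (single cells).  Colonies are unions of jittered disks
  with optional interior holes, a semi-transparent halo, class base
  colours and luminance noise, calibrated so each class's features fall
  inside published reference gate ranges; an `overlap_scale` knob
  emulates bloom heterogeneity.
* **IO, time series and CLI** (`colonygate.io`, `colonygate.pipeline`,
  `colonygate` console script) — CSV feature tables, plain-text filter
  files, per-(tank, date) abundance tables, and an end-to-end pipeline.

## Worked example

Train intergeneric filters (diameter + intensity, as used to separate
*Cryptomonas*, *Micractinium* and *Microcystis*) on a synthetic season
and score the intersection filter set on held-out particles:

```python
import numpy as np
from colonygate import (
    GenerationConfig, default_profiles, generate_dataset,
    build_filter_sets, apply_filters, evaluate_filter_set,
)
from colonygate.dataset import LabeledDataset
from colonygate import reference

config = GenerationConfig(profiles=default_profiles(), n_per_class=150, seed=0)
season = generate_dataset(config)            # 1050 labelled particles

classes = list(reference.INTERGENERIC_CLASSES)
panel = LabeledDataset(season.table[season.labels.isin(classes)]
                       .reset_index(drop=True))
filter_sets = build_filter_sets(panel, class_names=classes, seed=0,
                                feature_names=("Diameter (ABD)", "Intensity"))

inter = filter_sets["intersection"]
for f in inter.filters:
    print(f.class_name, [(n, round(lo, 2), round(hi, 2)) for n, lo, hi in f.gates])

train_rows = np.asarray(inter.metadata["training_rows"])
mask = np.ones(len(panel), bool); mask[train_rows] = False
test, train = panel.subset(mask), panel.subset(~mask)
report = evaluate_filter_set(apply_filters(inter, test),
                             training_result=apply_filters(inter, train))
print(report.per_class.round(3))
print({k: round(v, 4) for k, v in report.overall.items()})
```

prints

```
Cryptomonas [('Diameter (ABD)', 8.94, 11.18)]
Micractinium [('Diameter (ABD)', 17.83, 36.06)]
Microcystis novacekii [('Diameter (ABD)', 52.48, 78.27)]

                       hellinger_distance  balanced_accuracy_pct  smape_pct  precision  false_discovery_rate
Cryptomonas                           0.0                 95.732      4.459        1.0                   0.0
Micractinium                          0.0                 97.024      3.067        1.0                   0.0
Microcystis novacekii                 0.0                 95.122      5.128        1.0                   0.0

{'bray_curtis': 0.042, 'kl_divergence': 0.0001, 'hellinger_distance_mean': 0.0}
```

Gate reduction discovered that size alone separates the three genera on
this well-separated season (each filter kept a single diameter gate), so
every selection is pure (precision 1, FDR 0) and balanced accuracy per
class exceeds 95% — the shortfall from 100% is the min/max gates of 50
training particles clipping the tails of their own class.  The small
Bray–Curtis and KL values quantify how closely the predicted class
composition matches the true one; the zero Hellinger distances say the
training and test compositions of each classifier's selections agree.
Intrageneric separation of the five *Microcystis* morphospecies uses
more gates and scores visibly lower, especially with heterogeneity
(`overlap_scale=1`) — run `colonygate run --out demo/` to see it.

The same workflow is available from the shell:

```bash
colonygate generate --seed 3 --out demo/           # images or table + manifest
colonygate train --features demo/features.csv --n 50 --seed 1 --out f50.txt
colonygate classify --filters f50.txt --features demo/features.csv \
    --mode exclusive --out selections.csv
colonygate run --seed 0 --out pipeline_out/        # the whole pipeline
```

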