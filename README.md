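# remapkit

Simulation and analysis of **environment-specific voxel codes** — the fMRI
analogue of hippocampal remapping. The package is for researchers studying
how the human hippocampus keeps competing spatial memories apart: it
implements the full multivoxel analysis stack for a four-environment
retrieval design (two near-identical "similar" cities, an "interference"
city that re-uses their landmarks in a new layout, and a "distinct" city),
together with a synthetic-data generator so every stage is testable without
any scan data.

## What it computes

- **Synthetic cohorts** (`remapkit.synthetic`): per-city voxel templates,
  single-trial patterns with a tunable attraction mechanism (interference-city
  trials captured by the similar cities' codes), forward-modeled BOLD runs,
  and behavior coupled to the attraction rate.
- **Single-trial betas** (`remapkit.trialbeta`): FIR deconvolution (10 bins
  at TR = 3 s), empirical-HRF extraction by logistic-infomax ICA, cubic-spline
  resampling to 16 bins/scan, and a one-regressor-per-trial GLM.
- **Searchlight decoding** (`remapkit.searchlight`): 31-voxel ellipsoidal
  neighborhoods, split-half (block A/B) cross-validation, per-city accuracy
  and confusion structure, balanced-training variant.
- **Group inference** (`remapkit.inference`): one-sample t-maps against
  chance, max-cluster-size sign-flip permutation correction, and a bootstrap
  max-|t| threshold for families of condition-wise tests.
- **Pattern similarity** (`remapkit.mps`): trial-matched multivariate
  pattern similarity (Fisher z per pair), the **remapping index**

  > index(city) = z(within city) − mean z(between that city and the others),

  the incorrect-trial interference analysis, and a univariate activation
  control.
- **Behavioral scoring** (`remapkit.behavior`): per-city retrieval accuracy,
  map-learning slopes and transition costs, and the swapped-design chance
  bounds — with 9 of 20 trials conflicting between the similar cities, pure
  transfer caps at 55% and guess-on-conflicts chance is 77.5%.

A `remapkit` CLI (`simulate`, `searchlight`, `mps`, `behavior`, `run`) wraps
the library; `remapkit.pipeline.run_pipeline` orchestrates all stages from a
single seeded config.

## Worked example

Simulate 19 subjects in the interference regime (attraction probability
uniform on 0.15–0.65, mean 0.4; independent city templates) and run the
decoding and similarity analyses:

```python
import numpy as np
from remapkit.synthetic import simulate_cohort
from remapkit.searchlight import (classify_neighborhood, split_half_folds,
                                  misclassification_rate,
                                  behavior_classifier_correlation)
from remapkit.mps import similarity_matrix, remapping_indices

cohort = simulate_cohort(n_subjects=19, seed=1)
acc, mis, idx = [], [], []
for subj in cohort:
    ds = subj.dataset
    conf = classify_neighborhood(ds, np.arange(ds.n_voxels),
                                 folds=split_half_folds(ds))
    acc.append(conf.per_city_accuracy())
    mis.append(misclassification_rate(conf, 3, (1, 2)))
    idx.append(remapping_indices(similarity_matrix(ds)))
acc, idx = np.array(acc), np.array(idx)
r, p = behavior_classifier_correlation(
    np.array([s.behavior[3] for s in cohort]), acc[:, 2])
print("decoding accuracy per city :", np.round(acc.mean(0), 3))
print("City 3 trials labeled 1 or 2:", round(float(np.mean(mis)), 3))
print("remapping index per city    :", np.round(idx.mean(0), 4))
print(f"behavior vs City-3 decoding : r={r:.2f}, p={p:.1e}")
```

Output:

```
decoding accuracy per city : [0.801 0.767 0.186 0.788]
City 3 trials labeled 1 or 2: 0.657
remapping index per city    : [0.0393 0.0431 0.0058 0.0396]
behavior vs City-3 decoding : r=0.84, p=7.5e-06
```

Reading it: the three stable cities decode far above the 4-way chance of
0.25 while the interference city decodes *below* chance — its trials are
labeled as one of the two similar cities about 66% of the time (chance
would be 50%). The remapping index is positive for the stable cities
(their codes are reinstated within and separated between environments) and
near zero for the interference city, and subjects who retrieve the
interference city more accurately also decode it better. This is the
signature of attraction-driven interference: an unstable code losing the
retrieval competition to its stable neighbors.

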