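# otolookup

Content-based image retrieval (CBIR) for otoscopy images of the eardrum.

Diagnosing middle-ear conditions from an otoscope view is hard even for
experienced clinicians; first-line providers benefit more from seeing
*similar images with established diagnoses* than from a bare classifier
decision.  `otolookup` implements a retrieval approach built on exactly
that idea: **any CNN trained for classification can be converted into a
retrieval system** by reusing its final fully connected layer as a
projection into class-score space.

## The method

Let `f ∈ ℝ^F` be the pooled feature vector an image produces at the
CNN's global average-pooling layer, and `W ∈ ℝ^{F×C}`, `b ∈ ℝ^C` the
weights and bias of the final fully connected layer over `C` diagnostic
classes (here `C = 3`: middle-ear effusion, normal, tympanostomy tube).
Each database image contributes one row

    r = fᵀ W + b   ∈ ℝ^C

to the **lookup table** (an `N × C` matrix for `N` database images).  A
query image is projected the same way and its nearest rows are returned
under either of two distances:

    Chebyshev:  d(x, y) = max_j |x_j − y_j|
    Cosine:     d(x, y) = 1 − (x·y) / (‖x‖ ‖y‖)

Training is transfer learning: the convolutional stages stay frozen and
only the classification head is retrained on the target images.  The
package ships a small NumPy CNN (`TinyCNN`: three frozen seeded conv
blocks → global average pool → trainable FC head) that trains on a CPU
in seconds; the backbone contract is generic, so any model exposing
pooled features and an FC layer fits.

Around the core the package provides:

- `synthetic` — a generator of otoscopy-like test images: three
  color/texture-separable classes, exactly-black aperture margins,
  burned-in timestamp block, with a `separability` dial from identical
  class palettes (0) to disjoint hue ranges (1);
- `preprocess` — black-margin ROI detection/cropping, timestamp
  removal, random affine augmentation (flips, rotation, scale 0.7–2.0,
  shear 0–45°, translation ±30 px) and augmentation-based class
  balancing;
- `handcrafted` — the classic CBIR baseline descriptor
  `f1 = [HSV histogram | color autocorrelogram | color moments | Gabor]`
  with KNN/SVM score tables searched by the same machinery;
- `evaluation` — stratified k-fold harness measuring retrieval accuracy
  at k ∈ {1,3,5,7,9} under both metrics, with per-category
  precision/recall/F1 and mean ± SD aggregation across folds;
- `cli` — thin shell commands (`synth`, `preprocess`, `train`, `index`,
  `query`, `evaluate`, `baseline`) over the library.

## Worked example

```python
from otolookup import (SynthSpec, TinyCNN, TrainConfig, build_lookup,
                       extract_features, fine_tune, generate_dataset,
                       get_projection, project, retrieve)

images = generate_dataset(SynthSpec(n_per_class=22, separability=1.0, seed=8))
train = [im for im in images if int(im.id[-3:]) < 18]
val     = [im for im in images if 18 <= int(im.id[-3:]) < 20]
queries = [im for im in images if int(im.id[-3:]) >= 20]

model, history = fine_tune(TinyCNN(seed=8), train, val, TrainConfig(epochs=80, seed=8))
pw = get_projection(model)
feats = [extract_features(model, im) for im in train]
table = build_lookup(feats, [im.label for im in train], pw)

q = queries[0]
scores = project(extract_features(model, q), pw)
print(retrieve(scores, table, k=3, metric="chebyshev", query_id=q.id).items)
```

Output (from `python examples/03_train_and_retrieve.py`):

```
fine-tuned FC head: final validation accuracy 1.00
projection weights W: (32, 3) (features x classes), bias (3,)
lookup table: 54 rows x 3 class scores

query effusion-020 [effusion] via chebyshev: effusion-012(effusion, d=0.048), effusion-015(effusion, d=0.144), effusion-002(effusion, d=0.156)
query effusion-020 [effusion] via cosine   : effusion-008(effusion, d=0.000), effusion-010(effusion, d=0.000), effusion-012(effusion, d=0.000)
```

All three retrieved images share the query's diagnosis (effusion): the
nearest class-score rows come from same-class database images.  The
`examples/` directory holds one short script per capability, and the
same pipeline is scriptable from the shell:

```bash
otolookup synth --out data --n-per-class 20 --seed 7
otolookup preprocess --manifest data/manifest.csv --out prep
otolookup train --manifest prep/manifest.csv --out model.npz --seed 7
otolookup index --manifest prep/manifest.csv --checkpoint model.npz --out lookup.csv
otolookup query --image prep/normal-002.png --checkpoint model.npz --lookup lookup.csv --k 5 --metric cosine
otolookup evaluate --manifest prep/manifest.csv --folds 5 --seed 7 --out report/
```

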