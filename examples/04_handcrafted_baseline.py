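"""The classic CBIR baseline: handcrafted features + KNN score table.

The descriptor concatenates an HSV histogram, a color autocorrelogram,
the first two color moments per RGB channel, and Gabor wavelet
statistics.  A KNN classifier fitted on these vectors scores every
training image into class-vote fractions, giving a lookup table with
the same structure as the deep pipeline's, searched the same way.
"""

import numpy as np

from otolookup import (
    HandcraftedConfig,
    HandcraftedScaler,
    SynthSpec,
    baseline_score_table,
    compose_f1,
    compose_f1_matrix,
    generate_dataset,
    retrieve,
)

images = generate_dataset(SynthSpec(n_per_class=12, separability=1.0, seed=15))
train = [im for im in images if int(im.id[-3:]) < 10]
queries = [im for im in images if int(im.id[-3:]) >= 10]

config = HandcraftedConfig()
vec = compose_f1(train[0], config)
print(f"f1 vector length {len(vec.values)}; family spans:")
for name, (a, b) in vec.segments.items():
    print(f"  {name:16s} [{a:4d}, {b:4d})")

train_matrix = compose_f1_matrix(train, config)
scaler = HandcraftedScaler().fit(train_matrix)
table, score_fn = baseline_score_table(
    scaler.transform(train_matrix), [im.label for im in train],
    method="knn", params={"k": 5},
)

hits = 0
for q in queries:
    scores = score_fn(scaler.transform(compose_f1(q, config).values[None, :]))[0]
    res = retrieve(scores, table, k=1, metric="cosine", query_id=q.id)
    hits += res.items[0].label == q.label
print(f"\ntop-1 retrieval: {hits}/{len(queries)} queries returned a same-class image")
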