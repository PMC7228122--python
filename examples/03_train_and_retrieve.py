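"""Convert a trained classifier into an image retrieval system.

The FC layer's weights W (feature_dim x 3) project each database
image's pooled feature vector f into a 3-dimensional class-score vector
fᵀW + b; stacked, these form the lookup table.  A query image is
projected the same way and its nearest rows under Chebyshev or cosine
distance are the retrieved images.
"""

from otolookup import (
    SynthSpec,
    TinyCNN,
    TrainConfig,
    build_lookup,
    extract_features,
    fine_tune,
    generate_dataset,
    get_projection,
    project,
    retrieve,
)

images = generate_dataset(SynthSpec(n_per_class=22, separability=1.0, seed=8))
train = [im for im in images if int(im.id[-3:]) < 18]
val = [im for im in images if 18 <= int(im.id[-3:]) < 20]
queries = [im for im in images if int(im.id[-3:]) >= 20]

model, history = fine_tune(TinyCNN(seed=8), train, val, TrainConfig(epochs=80, seed=8))
print(f"fine-tuned FC head: final validation accuracy {history[-1]:.2f}")

pw = get_projection(model)
print(f"projection weights W: {pw.W.shape} (features x classes), bias {pw.b.shape}")

feats = [extract_features(model, im) for im in train]
table = build_lookup(feats, [im.label for im in train], pw)
print(f"lookup table: {table.rows.shape[0]} rows x {table.rows.shape[1]} class scores\n")

q = queries[0]
scores = project(extract_features(model, q), pw)
for metric in ("chebyshev", "cosine"):
    res = retrieve(scores, table, k=3, metric=metric, query_id=q.id)
    ranked = ", ".join(f"{it.id}({it.label}, d={it.distance:.3f})" for it in res.items)
    print(f"query {q.id} [{q.label}] via {metric:9s}: {ranked}")
# All top-3 labels matching the query's label means retrieval is working:
# the nearest class-score rows come from images of the same diagnosis.
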