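# parmds — parametric metric multidimensional scaling

`parmds` computes low-dimensional, distance-preserving embeddings of large
observation-by-feature matrices — the cells × genes matrices of bulk and
single-cell transcriptomics being the motivating case — together with an
**out-of-sample map**: a function that places previously unseen points into
the same embedding without re-optimizing.

## The problem and the method

Metric multidimensional scaling (mMDS) seeks points `y_1..y_n ∈ R^k`
minimizing the **stress**

    σ(Y) = Σ_{i,j} ( ‖x_i − x_j‖ − ‖y_i − y_j‖ )²  =  ‖D_X − D_Y‖_F² ,

the squared Frobenius discrepancy between the input and output distance
matrices. The standard solver, SMACOF (iterative stress majorization), has
quadratic time and memory in `n` and produces coordinates only for the
points it was given.

`parmds` instead trains a small fully-connected network — one tanh hidden
layer sized to the data's intrinsic dimension, linear output — with a
Siamese minibatch loss: within each batch of 256 points, the sum over all
unordered pairs of `(d(x_i, x_j) − ‖y_i − y_j‖)²` is minimized by Adam,
with the rows reshuffled every epoch so the sampled pairs estimate the full
distance matrix without ever materializing it. Training is linear in `n`
per epoch, and the fitted network *is* the embedding map `R^m → R^k`.

Comparators shipped alongside, all behind the same interface:

* **SMACOF** (Guttman-transform majorization, monotone stress trace);
* **classical MDS / PCA** (equivalent on explicitly given points);
* **Gaussian random projection** (Johnson–Lindenstrauss scaling `1/√k`);
* **projected metric MDS** — minimize stress subject to `Y = XP` linear,
  solved by smoothed L-BFGS from a PCA start, with the closed-form
  least-squares projection `P̃ = V₁Σ̃⁻¹U₁ᵀỸ` and its rank-dependent
  approximation bound `‖D_Ỹ − D_{XP̃}‖_F ≤ √(n−r+2)·‖D_Ỹ‖_F` available as
  diagnostics.

Supported input metrics: Euclidean, cosine, correlation. Supported file
formats: TSV/CSV and Matrix Market (the usual sparse scRNA-seq container),
with a transpose flag for genes × cells files.

## Worked example

The open box — points on the five faces of a lidless cube — is the
canonical shape a linear map cannot unfold but a nonlinear distance
preserver can:

```python
import numpy as np
from parmds import (NeuralMDS, open_box, pairwise_distances, stress,
                    pca_embed, random_projection)

box = open_box(n=1000, seed=0)                  # points on a lidless cube
D = pairwise_distances(box.X)                   # input-space distances

model = NeuralMDS(n_components=2, epochs=200, random_state=0).fit(box.X)
for name, Y in [
    ("neural MDS", model.embedding_),
    ("PCA", pca_embed(box.X, 2)[0]),
    ("random projection", random_projection(box.X, 2, seed=0)[0]),
]:
    s = stress(D, pairwise_distances(Y))
    print(f"{name:18s} stress = {s:10.1f}   relative = {s / np.sum(D**2):.4f}")

new_points = open_box(n=200, seed=1).X          # unseen data, same manifold
Y_new = model.transform(new_points)             # pure forward pass
print("out-of-sample embedding shape:", Y_new.shape)
```

prints

```
neural MDS         stress =    36934.0   relative = 0.0454
PCA                stress =    47794.0   relative = 0.0588
random projection  stress =   431874.3   relative = 0.5313
out-of-sample embedding shape: (200, 2)
```

The relative column is stress divided by `‖D_X‖_F²`, i.e. the fraction of
total squared distance the embedding fails to reproduce: the neural map
preserves the box's geometry noticeably better than the best
inner-product-preserving linear map (PCA), and vastly better than a random
projection. `model.transform` then embeds new points in milliseconds.

The same workflow is available from the shell:

```sh
parmds generate --kind box --n 1000 --seed 0 --output box.tsv
parmds fit --input box.tsv --output emb.tsv --method nn --dim 2 \
           --epochs 200 --seed 0 --model-out model.json
parmds stress --input box.tsv --embedding emb.tsv
parmds transform --model model.json --input box.tsv --output emb2.tsv
```

`--method` also accepts `pca`, `rp`, `smacof` and `projected`; a
`bound-check` subcommand verifies the linear-approximation bound for any
(data, embedding) pair.

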