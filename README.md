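# fmgda — Fréchet-mean Grassmann discriminant analysis

Supervised dimensionality reduction for data whose samples are
*subspaces* rather than vectors, with an EEG front-end for single-channel
epilepsy-detection experiments.

Many signals are naturally represented as a point on the Grassmann
manifold 𝒢(p, D) — the set of p-dimensional linear subspaces of ℝ^D.
An image set or a video clip becomes the span of its (vectorized) frames;
here, a single-channel EEG recording is cut into sub-epochs, each
sub-epoch yields an STFT log-power spectrogram, and the recording's
spectrograms span one subspace of the time–frequency feature space.
Classifying recordings then means classifying Grassmann points, which is
done with a 1-nearest-neighbour rule under the **projection metric**

    δ_P(X₁, X₂) = ½ ‖X₁X₁ᵀ − X₂X₂ᵀ‖²_F ,

where X ∈ ℝ^{D×p} is any orthonormal basis of the subspace.

The package's core, **FMGDA**, learns a mapping A ∈ ℝ^{D×d} (p ≤ d < D)
sending each point X to the orthonormalized columns of AᵀX in the
smaller manifold 𝒢(p, d).  Class centres are **Fréchet means** — under
δ_P the mean of {Xᵢ} is spanned by the top-p eigenvectors of Σᵢ XᵢXᵢᵀ —
and A maximizes the ratio of between-class to within-class spread,

    max_A  d_b(A) / d_w(A),
    d_b(A) = Σ_k n_k δ_P(f(M⁽ᵏ⁾,A), f(M,A)),
    d_w(A) = Σ_k Σ_i n_k δ_P(f(Xᵢ⁽ᵏ⁾,A), f(M⁽ᵏ⁾,A)),

solved by alternating between quadratic scatter surrogates (QR
normalizations frozen at the current A) and an iterated-eigenproblem
trace-ratio solver.  This is the Grassmannian analogue of Fisher LDA.

Intended users: researchers working with subspace-valued data (image
sets, videos, EEG/MEG spectrogram sets) who want a supervised,
projection-metric reduction step before nearest-neighbour
classification.

## Worked example

```python
import fmgda as fg

# three noisy classes of 5-dim subspaces in R^40, 30 points each
sim = fg.GrassmannSimSpec(n_classes=3, n_per_class=30, ambient_dim=40,
                          subspace_dim=5, noise=0.15, seed=0)
data = fg.gen_grassmann_classes(sim)

train, test = fg.stratified_split(data, ratio=0.5, seed=0)
model = fg.fit(train, fg.FMGDAConfig(target_dim=10))
print(f"objective d_b/d_w: {model.objective_trace[0]:.4f} -> "
      f"{model.objective_trace[-1]:.4f}")

acc = fg.knn_accuracy(fg.transform_set(model, train),
                      fg.transform_set(model, test))
base = fg.knn_accuracy(train, test)
print(f"1-NN accuracy after reduction (D=40 -> d=10): {acc:.3f}")
print(f"1-NN accuracy without reduction:             {base:.3f}")
```

prints

```
objective d_b/d_w: 0.0706 -> 0.1218
1-NN accuracy after reduction (D=40 -> d=10): 0.978
1-NN accuracy without reduction:             1.000
```

The fitted objective (between- over within-class spread) rises during the
alternating optimization, and 1-NN classification in the 4×-smaller
ambient space nearly matches the full-space baseline.

## EEG workflow from the shell

```sh
fmgda simulate  --out data/ --n-per-class 20 --seed 1     # Bonn-layout ASCII tree
fmgda featurize --data data/ --out features.json --p 4 --resize 7,13
fmgda grid      --features features.json --task five_class \
                --repeats 1 --seed 1 --out grid.csv
```

`simulate` writes five groups (folders Z/O/N/F/S ↔ groups A–E: healthy
eyes open/closed, two interictal conditions, ictal) of synthetic
single-channel recordings — 4097 samples at 173.61 Hz, matching the
Bonn archive layout, so the same `featurize` command works on the real
archive.  `grid` runs stratified splits at training ratios
0.1/0.2/0.4/0.6/0.8, fits FMGDA at each target dimension in
4…60, and writes a mean-accuracy table (rows = ratio, columns =
dimension).  `fmgda fit` and `fmgda eval` expose single fits and
evaluations of saved models.

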