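# frpsurv

Two-class survival prediction from immunohistochemistry (IHC) images via
**fuzzy recurrence plots** (FRPs) and a **bidirectional LSTM**, with linear
SVM and GLCM texture baselines.

## The problem and the method

Tissue dissected adjacent to a primary tumor ("normal tissue adjacent to
tumor", NAT) carries prognostic signal: IHC staining of protein expression
in NATs can separate patients who survive more vs less than 5 years after
surgery.  The cohorts involved are small (tens of images), which rules out
training a deep network end-to-end.  This package implements a pipeline
designed for exactly that regime:

1. **Deep features.** A pretrained-style CNN backbone (ResNet-101,
   DenseNet-201; NASNet-Large registered) is used as a fixed feature
   extractor; the flattened activation at the final global-average-pooling
   layer gives `g = (g₁,…,g_N)` with N = 2048 / 1920 / 4032.
2. **Compression.** Fuzzy c-means (FCM) with `c = n` clusters over the N
   scalar values of `g` yields the short sequence `x = (x₁,…,x_n)` of
   cluster centers, `n ≪ N` (default n = 13).
3. **Embedding.** Takens time-delay embedding (dimension d, delay τ) turns
   `x` into M = n − (d−1)τ phase-space states `sᵢ`.
4. **FRP.** A second FCM (c clusters, exponent m) over the states gives
   memberships µ(sᵢ, v_k); the FRP is

       F(i,j) = max_k min( µ(sᵢ,v_k), µ(s_j,v_k) ),   F(i,i) = 1,

   an M×M symmetric matrix with entries in [0,1] — a grayscale
   generalisation of a recurrence plot.
5. **Classification.** F is read as M time steps of M features and
   classified by a bidirectional LSTM (hidden size 100, Adam at lr 0.01,
   gradient clipping at norm 1, ≤300 epochs, full batch for small cohorts)
   into the two survival classes, positive = >5-year.

Defaults throughout: n = 13, FRP c = 3, m = 2, d = 1, τ = 1, FCM threshold
δ = 1e−5, max iterations Q = 100, so every image maps to a 13×13 FRP.
Evaluation is stratified 10-fold cross-validation reporting ACC, SEN, SPE,
PRE and F1 from pooled out-of-fold confusion counts.

The FCM, FRP construction, LSTM (including backpropagation through time)
and metrics are implemented from first principles in NumPy and pinned to
brute-force oracles in the test suite.  A seeded synthetic-data module
generates two-class stained-tissue-like images and class-structured
feature vectors (default cohort shape 29 negative / 51 positive), so the
whole pipeline is testable offline.  See
`docs/methods.md` for assumptions and design decisions.

## Worked example

```python
import numpy as np
from frpsurv import (
    BiLSTMClassifier, SyntheticFeatureConfig, TrainConfig,
    feature_to_frp, generate_features, run_cv_experiment,
)

# synthetic cohort: 29 negative / 51 positive, strong class signal
X, y = generate_features(SyntheticFeatureConfig(seed=0))

frp = feature_to_frp(X[0])          # compress -> embed -> FRP
print("FRP shape:", frp.values.shape)
print("corner:", np.array2string(frp.values[:3, :3], precision=3))

report = run_cv_experiment(
    [feature_to_frp(x) for x in X], y,
    lambda: BiLSTMClassifier(TrainConfig(seed=0)), k=10, seed=0)
print(report)
```

prints

```
FRP shape: (13, 13)
corner: [[1.    0.901 0.897]
 [0.901 1.    0.897]
 [0.897 0.897 1.   ]]
confusion: TP=51 TN=29 FP=0 FN=0 (P=51, N=29)
ACC=1.0000  SEN=1.0000  SPE=1.0000  PRE=1.0000  F1=1.0000
```

Each 2048-length feature vector became a 13×13 FRP (unit diagonal =
self-similarity; off-diagonal entries are fuzzy similarity grades between
embedded states).  With a strong synthetic effect size (2 sd on half the
coordinates) the cross-validated classifier recovers the class perfectly;
with effect size 0 accuracy drops to the 51/80 majority rate (see
`tests/test_acceptance.py`).

The same pipeline is available from the shell:

```bash
frpsurv simulate --mode images --out data/ --n-per-class 29 51 --seed 7
frpsurv extract  --images data/labels.csv --out feats/ --feature-mode glcm
frpsurv run-all  --out run/ --mode features --model lstm --seed 0
```

Every stage writes a `manifest.json` (resolved config, seed, package
version, SHA-256 of inputs/outputs) sufficient to reproduce it.

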