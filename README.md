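# spdalign

Transfer learning and prototype classification for symmetric
positive-definite (SPD) covariance matrices under the log-Euclidean
metric (LEM), with affine-invariant-metric (AIRM) baselines — the
covariance-based pipeline used for motor-imagery EEG decoding, fully
exercised on synthetic data.

## What's inside

| module | contents |
|---|---|
| `spdalign.geometry` | SPD-manifold primitives: matrix log/exp, LEM and AIRM distances, closed-form LEM mean, iterative Karcher (AIRM) mean, dispersions, geodesics, exp/log maps, matrix powers |
| `spdalign.alignment` | unsupervised domain alignment: `pa_lem` (log-domain standardization), `rpa_lem` (recenter + stretch with closed-form means), `rpa_airm` (AIRM baseline); transforms apply to batches or single new samples and serialize to JSON |
| `spdalign.plvq` | probabilistic prototype classifier with learnable log-domain metric tensor `Q = ΩΩᵀ` (stochastic gradient training, annealed schedules, 5-fold CV grid search) plus the minimum-distance-to-mean baseline |
| `spdalign.preprocessing` | epoched EEG → SPD covariances: window extraction, zero-phase Butterworth bandpass, per-trial covariance `E Eᵀ/(l−1)` |
| `spdalign.synthetic` | log-domain Gaussian mixtures on the SPD manifold with controlled covariance shift (log translation, dispersion scaling, congruence mixing), plus raw-epoch generators |
| `spdalign.evaluation` | balanced-class kappa, cross-session / cross-subject protocols, repetition bookkeeping, CPU-time comparison |
| `spdalign.cli` | `spdalign` command: `simulate`, `align`, `train`, `evaluate`, `benchmark-timing` |

## Quick start

```python
import numpy as np
from spdalign import synthetic as syn, alignment as al, plvq, evaluation as ev

# a 4-class benchmark with a composite covariance shift between domains
source, target, oracle = syn.standard_composite_benchmark(seed=0)

# unsupervised alignment (labels never touched during fitting)
t_src, t_tgt = al.fit_rpa_lem(source.without_labels(), target.without_labels())
src_aligned = source.with_matrices(al.apply_transform(t_src, source.without_labels()).matrices)
tgt_aligned = target.with_matrices(al.apply_transform(t_tgt, target.without_labels()).matrices)

# train on aligned source, score on aligned target
model = plvq.plvq_fit(src_aligned, n_per_class=1, sigma2=1.0, seed=0)
pred = plvq.plvq_predict(model, tgt_aligned)
print("kappa:", ev.kappa(target.labels, pred, 4))
```

Or end-to-end from the shell:

```bash
spdalign simulate --n 8 --classes 4 --n-per-class 60 --seed 0 --out runs/data
spdalign align --source runs/data/source.npz --target runs/data/target.npz \
               --method rpa_lem --out runs/aligned
spdalign evaluate --source runs/data/source.npz --target runs/data/target.npz \
                  --methods none,pa_lem,rpa_lem --classifier mdrm \
                  --runs 10 --out runs/eval
spdalign benchmark-timing --n 200 --size 22 --repeats 10
```

Every run writes its resolved configuration and a content hash next to
its outputs; results land as CSV plus a JSON summary.

## Conventions and noteworthy choices

- **No silent clipping.** Eigenvalues at or below `1e-12·λmax` raise
  `SingularMatrixError`; ridge-loading is opt-in (`geometry.regularize`,
  `trial_covariance(regularize=True)`).
- **Kappa** uses the balanced-class form `(D − 1/C)/(1 − 1/C)`.
- **Standardization divisor** in `pa_lem` is the root-mean-square log
  deviation, so both domains land at exactly unit dispersion.
- **Stretch dispersions** in `rpa_*` are computed on the recentered sets
  around the identity by default (`dispersion_order="post"`), which makes
  the dispersion-matching post-condition exact under LEM; pass
  `dispersion_order="pre"` for dispersions around each domain's own mean.
- **Rotation** (the third classical Procrustes step) is intentionally
  not implemented; per-class means are computed into `DomainStatistics`
  but unused.
- Alignment transforms and classifier models serialize to JSON
  losslessly (floats via `repr`).
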