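# morphodyn

Morphodynamical trajectory embedding for live-cell imaging: turn time-lapse
movies of segmented cells into a shared low-dimensional cell-state landscape
built from *trajectories* of morphology rather than single snapshots, and
quantify cell-state distributions, flows, metastability, and predictability
on that landscape.

## Who this is for

Researchers analyzing multi-condition live-cell imaging (e.g., phase-contrast
time-lapse of an epithelial line under different ligand treatments) who have,
or can generate, per-frame label masks from any segmentation backend, and who
want to ask: *do my conditions induce distinct cell states, and are the
transitions between those states systematic?*  No external dataset is needed
to develop against — the package ships simulators for both rendered movies
(with ground-truth masks and tracks) and feature trajectories with known
hidden-state dynamics.

## The method in brief

1. **Preprocess** — per-frame z-normalization with background forced to 0;
   translational (subpixel, no rotation) stack registration.
2. **Featurize** — each cell becomes a 91-dimensional vector: 49 Zernike
   moment magnitudes (degree ≤ 12), 12 Haralick texture statistics (13
   computed on a distance-1, direction-averaged GLCM; sum average dropped),
   15 boundary-Fourier shape features (|FFT| of the radial boundary profile,
   normalized to sum 1), and 15 cell-environment features (same Fourier
   treatment of a binary cell–cell contact indicator).  Pooled features are
   reduced by covariance PCA to n_pc = 3 components.
3. **Track** — two-regime, cluster-aware linking: nearest-centroid with a
   45 px cutoff inside foreground clusters < 10,000 px; cluster matching
   (300 px cutoff) + rigid registration + maximum mask overlap (≥ 10 px)
   for larger clusters.  Divisions appear as one parent with two children
   whose backward histories share the parental prefix.
4. **Embed** — every history of length T contributes T − n_τ + 1
   sliding-window snippets; the per-frame PCs of a snippet are concatenated
   into a supervector of length n_pc · n_τ (a cell tracked over 12 frames
   has 5 snippets of length 8).  Pooled supervectors are embedded with UMAP
   (d = 2 by default) into the shared landscape; a scrambled null (feature
   rows permuted within treatment) provides the no-temporal-information
   baseline.
5. **Dynamics** — on embedded snippet trajectories (T − n_τ transitions per
   history): overlap coefficient Σ min(p, q) between treatment
   distributions; locality ratio
   l = RMS(single-step displacement) / RMS(random-pair displacement)
   (1 for fully random motion, 0 for frozen, √(1−φ) for stationary AR(1));
   per-bin force-fields ⟨Δx⟩; a k-means microstate Markov model
   T_ij = C_ij / C_i with mean validation log-likelihood ⟨L⟩ = mean log T_ij;
   KDE density peaks grouped into kinetic macrostates; Bayesian-bootstrap
   confidence intervals over replicate splits.

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

Two simulated "treatments" share the same two-state feature distribution but
differ in switching dynamics (switch probability 0.45 vs 0.05); the most
state-informative feature dimension is withheld, so snapshots cannot
distinguish them.  Compare the snapshot embedding (n_τ = 1) with the
trajectory embedding (n_τ = 8):

```python
import numpy as np
from morphodyn.simulate import HiddenStateSimSpec, simulate_feature_trajectories
from morphodyn.embedding import sliding_windows, fit_embedding
from morphodyn.dynamics import mean_pairwise_overlap, locality_ratio

def simulate(switch_prob, seed):
    spec = HiddenStateSimSpec(
        n_states=2,
        state_means=[[-0.5, 0.0, -2.0], [0.5, 0.0, 2.0]],
        relaxation_rate=0.8, noise_sd=0.4,
        transition_matrix=[[1 - switch_prob, switch_prob],
                           [switch_prob, 1 - switch_prob]],
        n_cells=100, n_frames=25, observed_dims=(0, 1), seed=seed)
    return simulate_feature_trajectories(spec)[0]

fast, slow = simulate(0.45, 11), simulate(0.05, 22)

for n_tau in (1, 8):
    wf, ws = sliding_windows(fast, n_tau), sliding_windows(slow, n_tau)
    X = np.vstack([wf.reshape(-1, wf.shape[2]), ws.reshape(-1, ws.shape[2])])
    model = fit_embedding(X, d=2, seed=3)
    n_fast = wf.shape[0] * wf.shape[1]
    overlap, _ = mean_pairwise_overlap(
        {"fast": model.embedding_[:n_fast], "slow": model.embedding_[n_fast:]},
        bins=25)
    coords = model.embedding_[n_fast:].reshape(ws.shape[0], ws.shape[1], 2)
    loc = locality_ratio(list(coords))
    print(f"n_tau={n_tau}: overlap={overlap:.3f}  locality_ratio={loc:.3f}")
```

Output:

```
n_tau=1: overlap=0.776  locality_ratio=0.677
n_tau=8: overlap=0.439  locality_ratio=0.243
```

At the snapshot level the two conditions occupy largely overlapping regions
of the landscape (overlap 0.78); with 8-frame trajectory embedding their
distributions separate (overlap 0.44) and the persistent condition's
trajectories become far more predictable (locality ratio 0.24, where 1 means
fully random motion).  Scrambling feature rows in time (`morphodyn.embedding.
scramble_trajectories`) removes both effects.

## Command line

```bash
morphodyn run --out runs/demo --seed 1          # full pipeline on simulated movies
morphodyn simulate --out movie/ --n-cells 5 --n-frames 20 --seed 1
morphodyn track --masks movie/masks.tif --out links.jsonl
morphodyn report --run-dir runs/demo
```

`morphodyn run` executes simulate → preprocess → features → track → embed →
dynamics with content-hash caching: rerunning an unchanged config is a
no-op, and deleting an intermediate reruns only the downstream stages.

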