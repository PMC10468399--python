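# rhpkit

Population-based design of random heteropolymers (RHPs) as synthetic
mimics of protein mixtures. Individual RHP chains are statistically
sequence-defined — each chain has a different monomer order, but the
ensemble shares segmental statistics set by the monomer feed and the
reactivity ratios of the copolymerization. `rhpkit` implements the
sequence-analysis pipeline that makes this design quantitative, for
polymer chemists and protein scientists who want to compare polymer
ensembles with protein families at the level of 50-residue segments:

1. **Pseudo-residue reduction** (`rhpkit.alphabet`): protein and monomer
   sequences are reduced onto four classes — hydrophilic (P),
   hydrophobic (H), very hydrophobic (V), charged (C) — and each unit
   carries a hydrophilic–lipophilic balance (HLB) value on Griffin's
   0–20 scale.
2. **Windowing** (`rhpkit.sequence_io`): reduced sequences are cut into
   50-mers by a sliding window with 15-residue step and one-hot encoded.
3. **Ensemble simulation** (`rhpkit.chain_simulator`): Monte-Carlo
   growth of fixed-length chains (DP = 50) under terminal-model
   copolymerization kinetics with a shared finite monomer pool, so the
   feed drifts with conversion. The binary Mayo–Lewis closed form

       F1 = (r1 f1² + f1 f2) / (r1 f1² + 2 f1 f2 + r2 f2²)

   serves as the analytic cross-check of the simulator.
4. **Latent model** (`rhpkit.latent_model`): an autoencoder over one-hot
   50-mers (encoder 256/128/64 → 16-d latent z, sigmoid decoder) with a
   parallel regression head predicting each window's mean HLB, trained
   with loss `BCE + λ·(HLB_pred − HLB_true)²` (Adam, lr 1e-3,
   halve-on-plateau).
5. **2D projection and overlap** (`rhpkit.projection`): PCA of the
   latent vectors; PC1 tracks segmental hydrophobicity (sign-fixed so
   more hydrophobic segments sit at lower PC1), PC2 the sequential
   arrangement of blocks. Ensembles are summarized by Gaussian KDEs on
   a shared grid and compared by the Bhattacharyya coefficient
   Σ√(p·q) ∈ [0, 1].
6. **Biophysical calculators** (`rhpkit.physchem`): diffusion-limited
   collision kinetics (k_on = 4πDr), critical overlap concentration
   c* = 3M/(4πN_A R_g³), Guinier SAXS fits
   (ln I = ln I₀ − (R_g²/3)q²), sliding-window HLB profiles,
   Marko–Siggia worm-like-chain forces with unfolding-work integration,
   and exponential FRAP recovery fits R(t) = A(1 − e^(−t/τ)).
7. **Synthetic data** (`rhpkit.synthetic_data`): seeded generators for
   contrasting protein-like families and noisy SAXS/FRAP/force-extension
   curves, each the exact forward model of one fitter, so the whole
   pipeline is testable without downloads.

## Worked example

Closed-form anchors from the command line:

```console
$ rhpkit physchem cstar --m 36300 --rg 4.4
c* = 0.1689 g/cm^3 = 16.9 wt%
$ rhpkit physchem collision --d 50 --r 2 --c 2 --m 36000
k_on = 7.568e+08 M^-1 s^-1
dn/dt = 4.204e+04 s^-1
```

The first says a 36.3-kDa polymer coil of 4.4 nm radius only begins to
interpenetrate near 17 wt% — far above typical working concentrations
(0.2 wt%), so crowding is negligible. The second says polymer–protein
encounters at 2 g/l are of order 10⁵ s⁻¹, much faster than translation,
so transient interactions are not diffusion-limited.

End-to-end on synthetic families (membrane-like: long very-hydrophobic
blocks; globular-like: short alternating blocks):

```python
import numpy as np
from rhpkit import *
from rhpkit.alphabet import PSEUDO_CLASS_HLB
from rhpkit.sequence_io import extract_windows_many
from rhpkit.synthetic_data import make_benchmark_pair

membrane, globular = make_benchmark_pair(seed=301, n_sequences=200)
windows = extract_windows_many(membrane + globular)
labels = [sequence_hlb(w.letters, PSEUDO_CLASS_HLB)[1] for w in windows]
model, hist = train(windows, labels, ModelConfig(max_epochs=30, seed=302))
emb = model.encode(windows)
basis = fit_pca(emb)
coords = project(emb, basis)
is_mem = np.array([w.parent_id.startswith("membrane") for w in windows])
print(f"mean PC1 (membrane-like): {coords.pc1[is_mem].mean():.2f}")
print(f"mean PC1 (globular-like): {coords.pc1[~is_mem].mean():.2f}")
```

prints (3,921 windows, final validation loss 70.30):

```
mean PC1 (membrane-like): -3.00
mean PC1 (globular-like): 3.13
```

The very-hydrophobic family sits at lower PC1, i.e. the learned map
orders segments by hydrophobicity; the Bhattacharyya overlap between
the two family KDEs on a shared grid is 0.063 (near-disjoint, as built).
The same machinery projects simulated RHP ensembles into the protein
reference space to rank candidate feeds by overlap with a target family.

The CLI mirrors the library: `rhpkit synth | reduce | windows |
simulate | train | embed | project | compare | physchem …`, every run
writing delimited-text outputs plus a JSON manifest (config, seeds,
input digests) from which it can be reproduced.

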