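# rolodemix

Demixing and deconvolution of barcoded in-situ sequencing image stacks by
sparse non-negative regression.

## The problem

Multiplexed in-situ sequencing (e.g. BARseq-style experiments) reads out
gene identity optically: transcripts are amplified in place into *rolonies*
and imaged over `R` sequencing rounds in `C` color channels, so each gene
carries a barcode — a pattern of (round, channel) fluorescence recorded in a
binary codebook `B`. The observed stack `X[m, r, c]` (voxel, round, channel)
mixes the signal of all nearby rolonies, blurred by the microscope's
point-spread function and distorted by per-frame gains, channel cross-talk
and round-to-round phasing. Calling spots directly in such images is hard
when rolonies are dense or resolution is low.

`rolodemix` inverts a generative model of the stack,

```
X[m,r,c] ≈ a[m] + b[r,c] + Σ_j (K ∗ F[·,j])[m] · G[r,c,j]
G[r,c,j] = α[r,c] Σ_c' φ[c,c'] Z[r,c',j],      Z[r,c,j] = ρ[c] Z[r−1,c,j] + B[r,c,j]
```

where `F[m,j] ≥ 0` is the unknown per-barcode *rolony density*, `K` a
Gaussian PSF, `a`/`b` background and offsets, `α` per-frame gains, `φ`
channel cross-talk and `ρ` phasing ("ghosting" of one round into the next).
Estimation solves

```
min  L_sparsity   subject to   L_reconstruction ≤ ω,    all parameters ≥ 0
```

by block projected gradient descent, where `L_reconstruction` is the squared
error of the model and `L_sparsity` a linear penalty on the total summed
density. The result is a demixed, deconvolved image per barcode in which
rolonies are isolated local maxima. A detection threshold is calibrated with
*unused barcodes*: valid codes absent from the experiment whose fitted
densities can only be noise.

This is intended for registered, background-subtracted stacks — not raw
microscope output.

## Worked example

```python
import numpy as np
from rolodemix import (DemixingModel, SimConfig, augment_codebook,
                       default_codebook, default_true_params, match_spots,
                       render_stack, simulate_truth)

cfg = SimConfig(seed=3)                       # 7 rounds x 4 channels, 100x100, 30 rolonies
cb = augment_codebook(default_codebook(cfg), n_unused=2, seed=3)
truth = simulate_truth(cfg, cb)
stack = render_stack(truth, cb, default_true_params(cfg, cb.J), cfg.psf,
                     noise_sd=cfg.noise_sd, seed=4)

model = DemixingModel(stack, cb, psf=cfg.psf_sigma)
results = model.fit()
print(results.summary())
spots = results.call_spots()                   # threshold from the unused barcodes
m = match_spots(spots[spots.passes_threshold], truth, radius=2.0)
print(f"correct-barcode recovery: {m.correct_rate:.2f}  FPR: {m.fpr:.2f}")
```

prints

```
Barcode demixing fit
====================================================
rounds x channels          7 x 4
voxels, barcodes           10000, 12
converged                  True
outer iterations           15
reconstruction loss        105.707
noise threshold (omega)    111.332
sparsity penalty           1112.2
nonzero density entries    31
alpha (normalized) range   [0.0230, 0.0489]
phi off-diagonal max       0.0000
rho (phasing) max          0.0000
correct-barcode recovery: 1.00  FPR: 0.00
```

Read it as: the fit met its noise budget (reconstruction loss just under
ω), the per-frame gains span the simulated ramp after normalization, no
cross-talk or phasing was (correctly) detected, and every simulated rolony
was called at the right voxel with the right barcode with no false
positives.

The same pipeline is available from the shell:

```bash
rolodemix simulate --seed 1 --out-dir sim/
rolodemix fit --stack sim/stack.h5 --codebook sim/codebook.csv --out-dir out/ --seed 1
rolodemix benchmark --seed 1 --out roc.csv
```

`fit` writes the three standard outputs: `spots.csv` (all positive density
entries with a pass/fail flag), `diagnostics.h5` (per-spot rank-one SVD
quality scores and the fitted parameters) and `quality_histogram.csv/.png`.

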