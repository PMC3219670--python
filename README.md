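# emseg — spatially regularized Gaussian-mixture EM segmentation

`emseg` segments single-channel MRI-style images and volumes into tissue
classes with a Gaussian mixture model whose EM updates are regularized by
local neighbourhood information.  It is aimed at people working on brain-MRI
tissue classification (CSF / grey matter / white matter) and, more
generally, at anyone clustering noisy intensity images where spatially
adjacent pixels tend to belong to the same class.

## The model

Pixel intensities follow an M-component Gaussian mixture,
p(x_i | θ) = Σ_j α_j N(x_i; μ_j, Σ_j), fitted by expectation-maximization.
Plain EM looks at each pixel in isolation, so heavy noise shreds the label
map.  The spatial variant implemented here computes the neighbourhood-average
image x̄ *once*, before any iteration, and blends its density into the
likelihood with weight β:

    log L(θ | X) = Σ_i log Σ_j α_j [ (1−β) p_j(x_i | θ_j) + β p_j(x̄_i | θ_j) ]

The same blend enters the E-step, and the M-step mean and covariance updates
use (1−β)x_i + βx̄_i and d(x_i) + β·d(x̄_i) respectively, where
d(x) = (x − μ_j)(x − μ_j)ᵀ.  Because x̄ is precomputed, one iteration costs
essentially the same as plain EM.

β adapts itself to the image: magnitude-MRI background carries no signal, so
its Rician noise is Rayleigh-distributed, and the Rayleigh maximum-likelihood
estimate of the noise variance from n background pixels O_i is

    σ̂² = (1 / 2n) Σ O_i²

β is set to σ̂ on [0,1]-normalized intensities (clamped to [0, 0.5]).
Smoothing therefore grows with the noise level and vanishes on clean images,
which avoids the blurring penalty spatial regularization otherwise pays on
low-noise data.

The package also provides

- a **synthetic phantom generator** (nested disks, Voronoi blobs, fine
  stripes) with per-class Gaussian intensities, ground truth, and exact
  two-channel Rician noise — the test-bench for everything above;
- **evaluation metrics**: per-class and averaged Dice similarity index
  ρ = 2|X∩Y|/(|X|+|Y|), false-positive and false-negative ratios (both
  normalized by the truth class size), and Jaccard, with the usual
  protocol of excluding the background (the darkest predicted cluster);
- **split/merge refinement**: re-cluster an under-segmented cluster into two
  sub-clusters (children of cluster 3 are 31 and 32) and re-assign leaves to
  tissues, scripted and fully reproducible;
- NIfTI / PNG / TIFF I/O and an `emseg` command-line tool.

## Worked example

`examples/02_segment_spatial_vs_plain.py` builds a 64×64 four-label phantom
(background + three tissues at means 0 / 0.3 / 0.6 / 0.9), corrupts it with
9% Rician noise, and segments it both ways:

```
resolved beta          : 0.0637
Dice, plain GMM-EM     : 0.8167
Dice, spatial (EM-1)   : 0.8337
fitted means (spatial) : [0.122, 0.362, 0.634, 0.915]
```

β ≈ 0.064 is the estimated background noise level on the normalized
intensity scale; the spatial blend buys ~0.017 Dice at this noise level
while the fitted class means stay close to the truth (the upward shift of
the darker classes is the well-known Rician magnitude bias, not an EM
artefact).  The other examples cover phantom generation, noise estimation,
refinement and the shell pipeline; each prints what it computes and says
what the numbers mean.

The same pipeline from the shell:

```sh
emseg phantom --shape 64,64 --classes 4 --noise 9 --seed 1 \
      --out-image img.nii --out-truth truth.nii
emseg segment img.nii -M 4 --seed 2 --out-labels labels.nii --truth truth.nii
emseg evaluate labels.nii truth.nii --image img.nii
```

Runs are byte-reproducible for a fixed seed.

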