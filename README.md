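# fnlm — fast non-local means for color light-microscopy images

Stained histology specimens imaged under a light microscope carry noise from
the optics and from photon statistics, and classic smoothing filters remove
it only at the cost of blurring the very structures — nuclei, membranes,
stain boundaries — the image exists to show. Non-local means (NLM) avoids
that trade-off by replacing each pixel with a weighted average of the pixels
in a surrounding *search window*, where the weight of a candidate pixel n
for a target pixel m decays with the dissimilarity of the *patches* around
them:

    NL[f](m) = Σ_n w(m,n) f(n),
    w(m,n)   = exp(−‖v(k_m) − v(k_n)‖² / d²) / Z(m),

with `v(k_i)` the patch (kernel) of side `k` centred on i, `d` the smoothing
factor, and `Z(m)` the normalizer that makes the weights sum to one. Direct
evaluation costs O(search² · kernel²) per pixel. This package implements the
fast reformulation (FNLM): for each search-window displacement the field of
squared pixel differences is shared by every pixel, and a 2-D prefix
(integral) sum turns each patch distance into four corner lookups — the
per-pixel cost no longer depends on the patch size. A color image is split
into R, G, B channels, each channel is filtered with the same parameters,
and the channels are re-merged.

The package ships with:

- `fnlm.fast` — the integral-image FNLM filter (the production path);
- `fnlm.reference` — a literal brute-force NLM used as the correctness
  oracle (the two agree to ~1e-16 per pixel for uniform patch weights);
- `fnlm.metrics` — the evaluation stack: coefficient of variation (COV =
  σ/μ over a flat ROI), BRISQUE-style MSCN/AGGD feature extraction (36
  features; the opinion-score regressor is a pluggable component), and a
  NIQE-style multivariate-Gaussian distance with a pristine-corpus fitter;
- `fnlm.synthetic` — immunohistochemistry-like phantoms (brown
  immunopositive and blue hematoxylin-counterstained nuclei on a pale
  background) plus Gaussian/Poisson noise, so the whole pipeline is testable
  without proprietary microscopy data;
- a `fnlm` command-line tool with `denoise`, `evaluate`, `sweep`, `phantom`
  and `timing` subcommands.

## Worked example

```python
import numpy as np
from fnlm import (DenoiseParams, NoiseSpec, PhantomSpec, add_gaussian_noise,
                  color_luminance, cov_metric, fnlm_denoise_color,
                  generate_phantom, largest_background_rect)

clean, labels = generate_phantom(PhantomSpec(seed=7))          # 256x256 IHC phantom
noisy = add_gaussian_noise(clean, NoiseSpec(gaussian_sigma=0.05, seed=3))
roi = largest_background_rect(labels)                          # flat background ROI
params = DenoiseParams(d=0.03, kernel_size=7, search_size=21)
denoised = fnlm_denoise_color(noisy, params)

for name, img in [("noisy", noisy), ("denoised", denoised)]:
    cov = cov_metric(color_luminance(img), roi).cov
    mse = np.mean((img - clean) ** 2)
    print(f"{name:9s} background COV = {cov:.4f}   MSE vs clean = {mse:.2e}")
```

prints

```
noisy     background COV = 0.0331   MSE vs clean = 2.22e-03
denoised  background COV = 0.0111   MSE vs clean = 7.36e-04
```

The background coefficient of variation drops by 3× (the flat region is
genuinely flatter) and the mean squared error against the noiseless ground
truth falls by 3×: noise was removed, not just blurred away. Increasing `d`
flattens the background further but eventually degrades the no-reference
naturalness scores — the trade-off the `sweep` subcommand maps out:

```sh
fnlm phantom ph --gaussian-sigma 0.05 --seed 3
fnlm sweep ph.png --mode smoothing --labels ph_labels.png --output sweep.csv
```

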