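# vesselem

Automated extraction of blood vessels from retinal fundus images.

The pipeline has two stages. Pre-processing removes the smooth multiplicative
illumination inhomogeneity with an iterative log-domain bias-correction scheme
(histogram sharpening by Wiener deconvolution + cubic B-spline residual-field
smoothing in a multi-resolution schedule), enhances vessel/background contrast
with a windowed rank-based adaptive histogram equalisation, prunes noise with a
binary morphological opening, and converts the pruned mask into a Euclidean
distance map. The probabilistic stage classifies the distance-map pixels with
a two-component Gaussian mixture fitted by expectation maximisation, and a
length filter removes 8-connected components below a pixel-count threshold.

A seeded synthetic-phantom generator (tree-structured vessels with
Gaussian-shaped cross sections, low-frequency multiplicative bias, additive
noise, per-pixel ground truth) makes the whole pipeline testable without any
dataset download. Evaluation reports TPR / FPR / accuracy inside the field of
view.

## CLI

```sh
# generate a phantom (image, truth, fov, bias field, spec sidecar)
vesselem phantom --seed 1 --out phantom-out

# segment an image; metrics are computed when a truth mask is given
vesselem segment phantom-out/image.png \
    --fov phantom-out/fov.png --truth phantom-out/truth.png \
    --out seg-out --save-intermediates

# evaluate any prediction against a truth mask
vesselem evaluate seg-out/vessels.png phantom-out/truth.png --fov phantom-out/fov.png
```

`segment` accepts a YAML config with blocks `bias:`, `enhancement:`, `em:`,
`length_filter:` plus `channel:` and `invert:` (see
`vesselem.pipeline.PipelineConfig`). Exit codes: 0 success, 2 invalid input,
3 numerical failure.

## Library

```python
from vesselem import PhantomSpec, generate_phantom, run_pipeline

truth, centerlines, render = generate_phantom(PhantomSpec(seed=1))
result = run_pipeline(render.image, fov=render.fov, truth=truth)
print(result.metrics.tpr, result.metrics.fpr, result.metrics.accuracy)
```

Each stage is exposed on its own: `run_n4`, `adaptive_hist_eq`,
`binarize_and_open`, `distance_map`, `fit_em` / `e_step` / `m_step` /
`classify`, `label_components` / `filter_by_size`, `compute_metrics`,
`fov_mask_from_rgb`.

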