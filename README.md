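# wormglow

Anatomically aligned 2D fluorescence-intensity maps and average-intensity-independent
expression-pattern clustering for *C. elegans* micrographs.

## The scientific problem

Reporter-gene studies ask *where* in a worm a gene is expressed, not only *how much*.
Raw micrographs of different worms cannot be compared pixel by pixel: every animal lies
on the slide in a different pose (straight, C-shaped, S-shaped), faces a different
direction, and differs in size and overall brightness. Population-scale screens such as
flow sorting additionally report only a single brightness number per worm, hiding
spatial structure entirely.

wormglow converts each worm micrograph into a small, anatomically aligned **2D intensity
image** (default 75 × 15 cells): rows run head → tail, columns run across the body, and
the vulva side is always mapped to the rightmost column. On these aligned images,
position (row, column) means the same body location in every worm, so pixel-wise
comparison across animals becomes meaningful. Worms are then clustered by *expression
pattern* using a correlation-based distance that deliberately ignores average intensity,
so that dim worms with distinct spatial patterns are separated instead of being lumped
into one "dim" group.

## The model

The pipeline is a chain of explicit, testable stages:

1. **Pixel classification** (`wormglow.classify`): the micrograph is histogram-equalized;
   every pixel gets two features, the mean and relative standard deviation of its 5 × 5
   neighborhood (clipped at image borders); a logistic model scores each pixel as
   worm/background. The binary worm shape is chosen by sweeping thresholds 0.05–0.95 and
   keeping the most circle-like largest component occupying 3–25 % of the image, then
   refined (hole filling, 3× erosion + 3× dilation, excision of contour runs deviating
   from the local contour tangent — typically eggs clinging to the body).
2. **Meshing of image pairs** (`wormglow.mesh`): worms photographed as an anterior +
   posterior pair with overlap are registered by maximizing normalized cross-correlation
   (NCC) over integer shifts — a coarse pass on multiples of 16 px followed by an
   exhaustive ±16 px refinement — and exposure differences are removed with a linear
   brightness fit on the overlap. Head/tail follow from which image each skeleton
   endpoint came from; the vulva side is inferred from backbone convexity (the vulva
   lies on the inner side of a C-shaped worm), with a manual-annotation hook for
   straight/S-shaped worms.
3. **Straightening** (`wormglow.sampling`): the worm skeleton is reduced to a
   two-endpoint backbone, resampled to `h` equidistant points; at each point a
   border-to-border chord perpendicular to the backbone is split into `w` segments,
   forming an `h × w` grid of quadrangles whose mean raw intensities are the aligned
   image.
4. **Pattern clustering** (`wormglow.cluster`): pairwise distance `1 − NCC²` (invariant
   to any affine intensity transform) feeds average-linkage hierarchical clustering;
   cluster support is quantified with pvclust-style multiscale bootstrap resampling of
   pixel positions, reporting bootstrap probability (BP) and approximately unbiased
   (AU) confidence per dendrogram node. A Euclidean metric is included as a control —
   it clusters worms by brightness rather than pattern.
5. **Validation** (`wormglow.cluster.correlate_series`): per-worm mean intensities are
   correlated against an external per-worm measurement (e.g. a flow sorter).

Because no public micrographs exist for this protocol, `wormglow.synth` generates fully
ground-truthed synthetic worms: curved tapered bodies, planted Gaussian expression loci
in body coordinates, camera noise, anterior/posterior splits with known shift and
brightness mismatch, and populations with Bright/DimA/DimB/intermediate classes.

## Run the tests

```bash
python -m pytest -q tests/
```

The suite (~150 tests, a few minutes) checks every stage against independent oracles:
a brute-force Pearson formula for NCC, an exhaustive shift search, a naive O(n³)
agglomerative clusterer, explicit pixel scans for quadrangle averaging, and generator
ground truth for segmentation/straightening.

## Worked example

```python
import numpy as np
from wormglow import classify, cluster, sampling, synth

# render a worm with an expression locus at 45 % body length, off-vulva side
worm = synth.render_worm(synth.WormSpec(
    pose="c_shape", curvature=1.6, seed=7,
    loci=[synth.Locus(axial=0.45, lateral=-0.6, amplitude=1200.0)]))

# train a pixel model on three labeled worms, segment the new one
train = [synth.render_worm(synth.WormSpec(pose=p, curvature=c, seed=s,
         loci=[synth.Locus(0.5, 0.0, 500.0)]))
         for p, c, s in [("straight", 0.0, 1), ("c_shape", 1.5, 2),
                         ("s_shape", 1.3, 3)]]
model = classify.WormPixelClassifier().fit(
    [w.gfp for w in train], [w.truth_mask for w in train]).to_pixel_model()
labeled = classify.classify_worm(worm.gfp, model)

# straighten into the 75 x 15 anatomically aligned image
labeled.anatomy = worm.anatomy
img = sampling.sample_intensity_image(labeled, h=75, w=15)

# cluster a 60-worm synthetic population by pattern, with bootstrap support
pop = synth.generate_population(synth.PopulationSpec(seed=0))
pc = cluster.PatternClustering(metric="ncc_squared", n_clusters=3,
                               n_boot=200, seed=0).fit([s.pattern for s in pop])
for cls in ("Bright", "DimA", "DimB"):
    leaves = [i for i, s in enumerate(pop) if s.label == cls]
    jac, bp, au = pc.confidence_.best_match(leaves)
    print(f"{cls:>7}: AU = {au:5.1f}%  BP = {bp:5.1f}%  (n = {len(leaves)})")
```

Output:

```
segmentation Dice vs ground truth: 0.946
aligned image shape: (75, 15), brightest cell: row 33, col 3
mean intensity: 443.6 counts
 Bright: AU =  95.3%  BP =  79.0%  (n = 16)
   DimA: AU = 100.0%  BP = 100.0%  (n = 11)
   DimB: AU = 100.0%  BP = 100.0%  (n = 11)
```

(The first three lines come from `print` statements omitted above for brevity; the
brightest aligned cell sits at row 33 of 75 ≈ 45 % body length, in the left half —
exactly where the locus was planted. The Bright cluster's BP is only 79 % because the
22 intermediate-brightness worms blur its boundary; the multiscale AU extrapolation
corrects for exactly this and still supports the cluster at 95 %.)

The same pipeline is scriptable from the command line:

```bash
wormglow synth --out pop/ --seed 3 --no-render          # synthetic population
wormglow cluster --in 'pop/*.i2d.csv' --nboot 200 --out clust/
wormglow train-model --images imgs/ --labels masks/ --out model.json
wormglow classify --model model.json --in worm.tif --out labeled.png
wormglow mesh --anterior a.png --posterior p.png --out fused.png
wormglow sample --in fused.png --out worm.i2d.csv
wormglow validate --in 'out/*.i2d.csv' --reference sorter.csv --out r.json
wormglow run --config run.yaml --manifest manifest.csv   # end to end
```

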