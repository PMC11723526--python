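# myoseg

Simultaneous **myotube and nuclei segmentation** of two-channel fluorescence
micrographs, with watershed/skeleton post-processing that turns probability
maps into per-myotube morphometry: **diameter (μm), length (μm), and nuclei
count**.

Myotubes are multinucleated muscle fibres (myosin heavy chain stain,
channel 0); nuclei are DAPI-stained blobs (channel 1) that frequently
overlap. Global intensity thresholds fail on such images — uneven
illumination lets bright background outshine dim fibre ends — and plain
semantic segmentation cannot split touching nuclei or measure fibre width.
`myoseg` addresses both with a three-headed network plus classical
instance-level post-processing, and ships a synthetic scene generator with
exact ground truth so the entire pipeline is testable offline.

## Method

**Network.** A residual encoder–decoder `G` with three class heads `C_k`
(5×5 conv + sigmoid) produces aligned probability maps

```
ŷ_k = C_k(G(x)),   k ∈ {myotube mask, nuclei mask, nuclei centroid}
```

from a 2-channel patch `x`. `G` = two 3×3 stride-2 down-blocks
(instance norm + ReLU; 2→64→128 channels for 512×512 inputs), a stack of
five residual blocks (conv–BN–ReLU–conv–BN + identity, 256 channels via a
1×1 projection), and two 3×3 stride-2 transposed-conv up-blocks
(instance norm + LeakyReLU; 256→128→64). Training minimises the weighted
per-class binary cross-entropy

```
L_total = λ₁·L_myotube + λ₂·L_nuclei + λ₃·L_centroid,
L_k = −(1/N) Σ_i [ y_i log ŷ_i + (1−y_i) log(1−ŷ_i) ]
```

with Adam (lr 0.001, β₁ = 0.5, β₂ = 0.999). The layers and backward passes
are implemented directly on numpy (`myoseg._nn`), verified by
finite-difference gradient checks.

**Post-processing.** Overlapping nuclei are split by a marker-controlled
watershed: predicted centroids and far-background become markers, the
remaining pixels are flooded in order of the negated distance transform,
and pixels where two floods meet become the watershed line `WL` separating
instances. Myotube masks are thinned to one-pixel skeletons (Lee-style
medial-axis peeling), decomposed into branches at junction pixels
(≥3 skeleton neighbours), and the local width `2·EDT − 1` is sampled along
each branch; branch length uses 1/√2 steps. Nuclei are assigned to the
myotube whose mask contains their instance centroid.

**Evaluation.** IoU = TP/(TP+FP+FN) and Dice = 2TP/(2TP+FP+FN), image-level
5-fold cross-validation folds, and six classical auto-threshold baselines
(IsoData, Li, Mean, Minimum, Otsu, Yen) for comparison tables.

## Worked example

```python
import numpy as np
import myoseg as ms

# a synthetic 128x128 scene: 2 curved tubes, 12 partly-overlapping nuclei
img, gt = ms.generate_scene(ms.gradient_scene_spec(seed=8))

# feed exact masks through the instance pipeline
records = ms.quantify_image(
    (gt.myotube_mask.astype(np.float32),
     gt.nuclei_mask.astype(np.float32),
     gt.centroid_mask.astype(np.float32)))
for r in records:
    if r.branch_id == -1:   # per-myotube rollup rows
        print(f"myotube {r.myotube_id}: diameter {r.diameter_um:.1f} um, "
              f"length {r.length_um:.1f} um, nuclei {r.n_nuclei}")
```

prints (μm/px = 1):

```
myotube 1: diameter 9.5 um, length 142.5 um, nuclei 1
myotube 2: diameter 7.6 um, length 114.6 um, nuclei 0
```

The generator drew these two tubes with stroke widths 10 and 8 px, so the
measured diameters recover the ground truth within ±1 px; the first fibre
contains one nucleus centroid along its 142-px skeleton. Training, prediction, baseline comparison and group
summaries are available both as library calls and through the CLI:

```sh
myoseg simulate --out-dir data --n-scenes 10
myoseg train --manifest data/manifest.csv --checkpoint model.npz --epochs 16
myoseg quantify --config pipeline.yaml
```

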