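# mtsaquant

Quantitative assessment of inflammatory infiltrates in multiplex
tyramide-signal-amplification (mTSA) stained kidney transplant biopsies.

Multiplexed immunofluorescence lets one tissue section carry a whole antibody
panel (e.g. CD3, CD4, CD8, CD20, CD68, CD34, or CD4, Tbet, GATA3, CD68,
CD163 plus a DAPI counterstain), imaged multispectrally as tiles. `mtsaquant`
implements the downstream computational pipeline:

1. **Spectral unmixing** — each pixel's band spectrum `p ∈ R^B` is modelled
   as a non-negative mixture of known fluorophore emission spectra
   `S ∈ R^{B×F}` from a prerecorded spectral library; abundances solve
   `min_{a ≥ 0} ||S a − p||²` (per-pixel non-negative least squares).
2. **Stitching** — unmixed single-fluorophore tile planes are mosaicked into
   whole-slide planes by their stored origins.
3. **Artificial brightfield IHC** — a DAPI plane plus one marker plane are
   recoloured as a virtual hematoxylin/DAB slide through the Beer–Lambert
   law, per RGB channel `ch`:

   `out_ch = 255 · exp(−(I_DAPI · c_ch,Hem + I_IHC · c_ch,DAB))`

   with Ruifrok–Johnston stain vectors by default, so detectors built for
   conventional chromogenic IHC can run on fluorescence data.
4. **Detection decoding & evaluation** — probability maps are thresholded
   and reduced to component centroids; box grids go through greedy
   non-maximum suppression. Detections are matched one-to-one to dot
   annotations within one average cell diameter (4 µm lymphocytes, 21 µm
   macrophages) in ascending distance order, so only the closest detection is
   credited; precision, recall and F1 = 2PR/(P+R) follow from the matched
   counts. A Laplacian-of-Gaussian reference detector stands in for trained
   networks on synthetic scenes.
5. **Spatial quantification** — ROI handling (cortical tubulointerstitium
   minus glomeruli/arteries/capsule, with optional exclusion of the 400 µm
   subcapsular band), cell densities in cells/mm², double positivity
   (paired detections closer than one cell diameter), derived populations by
   geometric subtraction (CD3⁺CD8⁻), mean shortest nearest-neighbour
   distances, and positive-pixel percentage of a marker plane (peritubular
   capillary extent for CD34).
6. **Cohort statistics** — exact small-sample Mann–Whitney U, Spearman
   correlation, Wilcoxon signed-rank, independent t-test, Fisher's exact,
   and median (min–max) / mean (SD) group summaries.

A synthetic-scene generator (`mtsaquant.synthetic`) plants cells with known
marker memberships, co-localization fractions and a capillary mask, and
renders them through a known spectral library — optionally with noise and
spectral bleed-through — so the whole pipeline is testable end to end with
no external data.

## Worked example

```python
from mtsaquant.synthetic import generate_scene, default_spectral_library, RenderConfig
from mtsaquant.pipeline import run_end_to_end

scene = generate_scene(
    {"CD4": 70, "CD68": 20, "CD163": 8},
    {("CD68", "CD163"): 0.5, ("CD4", "GATA3"): 0.3},
    scene_size_um=550.0, seed=33,
)
cfg = RenderConfig(library=default_spectral_library(panel=2))
result = run_end_to_end(scene, cfg)
for marker, pop in result["populations"].items():
    print(marker, pop.n_truth, pop.n_detected, round(pop.f1, 3),
          round(pop.density_detected, 1))
print(result["coloc"])
```

prints

```
CD4 70 70 1.0 280.0
CD68 20 20 1.0 80.0
GATA3 21 21 1.0 84.0
CD163 18 18 1.0 72.0
{('CD163', 'CD68'): (10, 10), ('CD4', 'GATA3'): (21, 21)}
```

i.e. on a noise-free rendered scene every planted cell of every population is
recovered through unmix → stitch → brightfield conversion → detection
(F1 = 1.0), densities (cells/mm², last column) match the planted counts over
the ROI area, and the planted double-positive counts (10 CD68⁺CD163⁺,
21 CD4⁺GATA3⁺) are recovered exactly.

The same workflow is available from the shell:

```bash
mtsaquant simulate --config cfg.json --seed 5 --out sim/
mtsaquant unmix --library sim/library.json --tiles sim/ --out unmixed/
mtsaquant stitch --planes unmixed/ --canvas 1122x1122 --out wsi/
mtsaquant convert --dapi wsi/wsi_DAPI.tif --marker wsi/wsi_Opal520.tif --out cd4_bf.tif
mtsaquant detect --mode blob --plane wsi/wsi_Opal520.tif --out cd4_dets.csv
mtsaquant evaluate --detections cd4_dets.csv --annotations sim/annotations.xml --out scores.csv
mtsaquant quantify --roi sim/annotations.xml --detections cd4_dets.csv --out quant.csv
mtsaquant stats --groups groups.csv --quant quant.csv --out stats.csv
```

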