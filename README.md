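# myddo

Quantification of Myddosome assembly dynamics from live-cell TIRF imaging.

Innate-immune signaling through IL-1 receptors proceeds by the inducible
assembly of the Myddosome, a supramolecular complex in which the adaptor
MyD88 oligomerizes at activated receptors and then sequentially recruits the
kinases IRAK4 and IRAK1. In TIRF movies of cells on ligand-functionalized
supported lipid bilayers, each nascent Myddosome appears as a
diffraction-limited GFP punctum whose brightness reports its MyD88 copy
number. `myddo` implements the image-quantification pipeline for this assay
— and a synthetic-data generator with exhaustive ground truth, so every
stage of the pipeline is verifiable without the original microscope data.

## What the package computes

**Copy-number estimation.** The single-GFP unit intensity is calibrated
from sparse purified GFP adsorbed to glass, imaged and measured identically
to cellular data (dark-frame subtraction, 25 px disk-median background
subtraction, 3×3-pixel intensity sums at tracked spot centers). A punctum
containing *N* GFPs is modelled as Gaussian with mean and variance both *N*
times the single-GFP values,

> X<sub>N</sub> ~ Normal(N·μ, N·σ²),

so a maximum-intensity threshold of **4.5× GFP** separates "small"
(monomer–trimer) from "large" (>4 MyD88) oligomers while capturing more
than 98 % of hexamers at realistic calibration CVs.

**Pipeline stages** (each a module, composable as sklearn-style
transformers/estimators or via plain functions):

| stage | module | contents |
|---|---|---|
| synthetic data | `myddo.simulate` | TIRF movie generator (Poisson nucleation, birth–death oligomer kinetics, pixel-integrated Gaussian PSF, offset+Poisson+read-noise camera), calibration stacks, FRAP traces, fixed-cell fields |
| corrections | `myddo.preprocess` | dark frame, disk-median background, illumination flattening |
| tracking | `myddo.tracking` | LoG spot detection with sub-pixel centers, greedy mutual-nearest linking with gap closing, 3×3 intensity measurement, ≥3-frame filter |
| stoichiometry | `myddo.stoichiometry` | `GfpCalibrator` (robust unit-intensity fit), N-mer model, `OligomerSizeClassifier` (4.5× rule) |
| analytics | `myddo.metrics` | lifetimes (short <50 s / long ≥50 s), growth Δ = (max − initial)/μ with the <2.5× nucleation screen, Spearman lifetime–growth correlation, per-cell summaries |
| colocalization | `myddo.coloc` | two-channel track pairing (≤0.25 µm for ≥2 consecutive frames), recruitment times, partner-positive vs. -negative size comparison |
| FRAP | `myddo.frap` | (I(t) − I(0)) / (I(pre) − I(0)) normalization, recovery statistics, trace averaging |
| fixed cells | `myddo.fixedcell` | marker-controlled watershed nucleus/cytoplasm segmentation, morphology and crowding filters, nuclear/cytoplasmic translocation ratios |

## Worked example

```python
import numpy as np
from myddo import (SimulationConfig, simulate_puncta_movie, render_nmer_field,
                   analyze_movie, calibrate_from_movie, compute_track_metrics,
                   lifetime_growth_correlation, summarize_cell)

cfg = SimulationConfig(image_shape=(128, 128), n_frames=120,
                       nucleation_rate=0.5, min_separation_px=12, seed=42)

# calibration: a field of single GFPs measured through the identical pipeline
cal_movie, _ = render_nmer_field(cfg, n_monomers=1, n_spots=64, n_frames=4)
model = calibrate_from_movie(cal_movie, dark=cfg.camera_offset)

# live-cell movie: detect, link, measure, filter
movie, truth = simulate_puncta_movie(cfg)
tracks = analyze_movie(movie, dark=cfg.camera_offset)

metrics = compute_track_metrics(tracks, model, cfg.frame_interval_s)
summary = summarize_cell(metrics)
print(f"{len(tracks)} tracks; {summary.pct_large:.1f}% large (>=4.5x GFP)")
print(f"large among long-lived: {summary.pct_large_long}")
r, p = lifetime_growth_correlation(metrics)
print(f"lifetime-growth Spearman R = {r:.2f} (p = {p:.2g})")
```

Output:

```
38 tracks; 18.4% large (>=4.5x GFP)
large among long-lived: 100.0
lifetime-growth Spearman R = 0.61 (p = 0.0027)
```

Thirty-eight puncta survive the three-frame filter; about 18 % ever exceed
4.5× GFP, every long-lived (≥50 s) punctum in this movie is a large
oligomer, and intensity growth correlates positively with lifetime — the
two-population structure (transient small oligomers vs. stable growing
ones) that the generator encodes and the pipeline recovers.

The same steps are available from the shell:

```sh
myddo simulate movie --seed 42 --out out/
myddo track --in out/movie_C0.tif --out out/tracks.csv
myddo calibrate --in out/calibration_C0.tif --out out/calib.json
myddo classify --tracks out/tracks.csv --calib out/calib.json --out out/classified.csv
```

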