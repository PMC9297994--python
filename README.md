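# sinter4d

Automated 4D (3D + time) micro-CT image analysis of sintering inside
3D-printed glass and ceramic scaffolds.

Additively manufactured bioactive-glass scaffolds are printed as "green"
bodies — woodpile lattices of particle-packed struts — and then sintered.
Sintering densifies the glass and shrinks the lattice, which distorts the
printed architecture. In situ synchrotron micro-CT can film the process,
but turning ~100 reconstructed 3D volumes into numbers requires an
automated pipeline. `sinter4d` provides one, for researchers in
biomaterials and ceramics processing who need reproducible, validated 4D
quantification:

* **detects and tracks** strut-slice volumes of interest (VOIs) across the
  time series (slice classification → 2D level sets → 3D connected
  components → minimum-distance center linking into 4D "hyperstacks");
* **segments** the glassy phase — a 200-tree random forest over a
  77-attribute multi-scale feature bank while glass/pore histograms
  overlap, Otsu thresholding once densification passes ~90% — and the
  strut outline (per-slice level set with pore filling);
* **quantifies** the descriptors of sintering:

  - intrastrut porosity and relative density of the glassy phase,
    `Porosity% = Pore/(Pore+Glass) × 100`, `RelativeDensity% = 100 − Porosity%`;
  - strut diameter from the cross-sectional area, `D = 2·√(A/π)`;
  - interstrut pore diagonal distance, `PDD = center distance (diagonal, in-plane) − D`;
  - isotropic volume shrinkage from linear shrinkage, `ΔV/V = 1 − (1 − s)³`,
    plus measured (bounding-box) shrinkage and layer-to-layer strut overlap;
  - classical sintering-stage annotation (initial / intermediate / final).

A first-class synthetic module (`sinter4d.phantom`) generates woodpile
phantoms — particle-packed struts that densify and shrink over simulated
time under realistic imaging noise — with voxel-aligned ground truth, so
the entire pipeline is testable end to end without any scan data.

## Worked example

Analyze a small synthetic sintering series end to end (about half a
minute):

```python
from sinter4d import pipeline as pl
from sinter4d.cli import small_phantom_spec

result = pl.run_phantom_pipeline(small_phantom_spec(seed=3))
cols = ["time_index", "segmenter", "density_pct", "truth_voi_density_pct",
        "diameter_px", "true_diameter_px"]
print(result.table[cols].round(2).to_string(index=False))
print("tracked:", result.tracked_fraction_pct)
```

```
 time_index segmenter  density_pct  truth_voi_density_pct  diameter_px  true_diameter_px
          0        rf        61.43                  60.91        25.03             23.70
          1        rf        63.63                  63.09        25.03             23.79
          2        rf        78.91                  78.04        22.62             22.57
          3        rf        82.88                  82.61        21.37             21.65
          4        rf        86.44                  86.27        21.36             21.59
tracked: 100.0
```

Reading it: every strut segment of the phantom was tracked through all
five scans; the measured relative density of the glassy phase
(`density_pct`, random-forest segmentation) follows the true glass
fraction in the same VOIs (`truth_voi_density_pct`) to within a
percentage point as the phantom densifies, and the measured strut
diameter tracks the programmed shrinkage of the ~24-voxel struts to
within about a voxel.

The closed-form descriptors work on published geometry directly:

```python
from sinter4d import quantify as q
q.strut_overlap(241.4, 200.0)          # (41.4, 17.15): µm overlap, % of diameter
q.volume_shrinkage_isotropic(0.158)    # 0.40305: 15.8% linear -> 40.3% volume
```

## Command line

```bash
sinter4d phantom --seed 1 --out data/          # ground-truthed TIFF series + manifest
sinter4d train --seed 1 --out classifiers/     # slice SVM + voxel forest
sinter4d run --config pipeline.yaml            # full analysis -> series.csv + plots
sinter4d quantify --mask strut_mask.tif        # diameter from an existing mask
sinter4d evaluate --predicted p.tif --truth t.tif   # IoU / accuracy / precision
```

Real scan series are described by a CSV manifest
(`scan_id,time_s,temperature_C`) next to multi-page TIFF volumes; the
pipeline config is YAML (see `sinter4d.pipeline.validate_config` for the
schema and defaults: 0.25 resampling, 200 trees, 90% segmenter switch,
0.81 µm voxels).

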