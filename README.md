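# nanofish

Nanometer-scale separation measurement of two-color RNA-FISH transcription
foci imaged on a conventional widefield microscope.

Intronic FISH probes mark nascent transcripts at their gene locus. Two
probe sets in different colors label two regions of the same gene; each
focus is a diffraction-limited spot (~200 nm) whose *center* can be
localized an order of magnitude more precisely than the diffraction limit.
`nanofish` implements the full measurement chain:

1. **Spot QC** — candidate foci must be Gaussian-like, ≥3x brighter than
   background, and locally contrasted;
2. **Sub-pixel localization** — least-squares fitting of an elliptical 2D
   Gaussian `F(x,y) = z0 + A·exp(−[((x−x0)/sx)² + ((y−y0)/sy)²]/2)`
   (plus centroid and Poisson maximum-likelihood estimators), initialized
   from the brightest pixel and the theoretical PSF width
   `s = 0.21·λ/NA`, iterated to a 0.01% tolerance;
3. **Precision** — per focus, `σ² = s²/N + a²/12N + 8πs⁴b²/a²N²`
   (N detected photons, a pixel size, b background noise);
4. **Chromatic registration** — a local-weighted-mean transform built from
   ≥12 multi-spectral fiducial beads, with the residual misalignment `r`
   measured on held-out beads;
5. **Separation** — paired two-color foci give `d` with combined
   uncertainty `√(σ_A² + σ_B² + r²)`; `d` is significant only above that;
   populations are summarized as 30-nm-bin histograms with area-normalized
   Gaussian fits;
6. **Probe design** — GC-matched 50-mer windows, fluor-spacing assignment,
   20-mer genome-uniqueness screening, and ≤600-nt span assembly;
7. **Synthetic imaging** — a ground-truth generator (integrated-Gaussian
   PSF, Poisson/read-noise camera, chromatic warps) so every stage is
   testable without a microscope.

See `docs/methods.md` for the models, defaults, and their rationale.

## Worked example

Simulate two-color scenes, build a registration model from beads, and
measure separations:

```python
import numpy as np
from nanofish.core import FrameGeometry, NoiseModel, OpticsModel
from nanofish.pipeline import localize_image, measure_separations
from nanofish.register import build_lwm_transform, match_fiducials, residual_error
from nanofish.separation import fit_histogram_gaussian, histogram_separations
from nanofish.synthetic import (ChannelWarp, make_colocalized_pairs,
                                render_bead_field, render_nucleus_scene)

frame = FrameGeometry(128, 128, pixel_size_nm=200.0)
optics = {"A": OpticsModel(615.0, 1.45), "B": OpticsModel(684.0, 1.45)}
noise = NoiseModel(background_photons_per_px=10.0)
rng = np.random.default_rng(123)
warp = ChannelWarp.random_quadratic(frame, max_displacement_nm=30.0, rng=rng)

# chromatic registration from a bead field
images, _ = render_bead_field(45, warp, frame, optics, noise, seed=1, photons=20000)
fits = {ch: localize_image(images[ch]) for ch in "AB"}
pairs = match_fiducials(*[np.array([[f.x0_nm, f.y0_nm] for f in fits[ch]]) for ch in "AB"])
model = build_lwm_transform(pairs[:-10], pixel_size_nm=200.0)
r = residual_error(model, pairs[-10:])

# a scene of 18 two-color pairs at a true 68-nm separation
prs = make_colocalized_pairs(18, 68.0, frame, photons=20000, rng=rng,
                             min_pair_spacing_nm=2600, margin_nm=1200)
imgs, _ = render_nucleus_scene(prs, frame, optics, noise, warp, seed=2)
records = measure_separations(localize_image(imgs["A"]), localize_image(imgs["B"]),
                              model, r_nm=r)
g = fit_histogram_gaussian(histogram_separations(records, bin_width_nm=4.0))
u = float(np.mean([rec.combined_uncertainty_nm for rec in records]))
print(f"r = {r:.2f} nm; {len(records)} pairs; fitted mean = {g.mean_nm:.1f} nm; "
      f"combined uncertainty = {u:.1f} nm")
```

Output:

```
r = 2.29 nm; 18 pairs; fitted mean = 68.0 nm; combined uncertainty = 3.5 nm
```

The registration residual (2.3 nm here, bead-photon-limited) is propagated
into every record's combined uncertainty; the fitted histogram mean
recovers the true 68-nm separation well within it.

The same workflow is available from the shell:

```
nanofish simulate --config scenes.yaml --out-dir sim/
nanofish register --beads-a beads_A.tif --beads-b beads_B.tif \
                  --config config.yaml --out-model model.tsv
nanofish measure  --image-a sim/scene000_A.tif --image-b sim/scene000_B.tif \
                  --model model.tsv --config config.yaml --out-dir out/
nanofish probes   --target intron.fa --background genome.fa --out probes.tsv
```

All tables are TSV with a provenance header (config fingerprint, seed,
thresholds); images are 16-bit TIFF.

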