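# ionbridge

Analysis toolkit for **ion-induced clustering of anionic membrane
proteins**: how divalent cations such as Ca²⁺ first aggregate a
negatively charged protein (by bridging its carboxylate groups) and then
re-disperse it at high concentration (by saturating and overcharging
them). The package is written for people who quantify this behaviour from
two kinds of raw material:

* **fluorescence micrographs of membrane sheets** — background-corrected
  intensity, the relative standard deviation (coefficient of variation)
  of the stain as a segmentation-free clustering metric, ImageJ-style
  find-maxima cluster densities, pixel-shift Pearson autocorrelation with
  a 50 %-decay cluster radius, and the fraction of signal in punctate
  areas;
* **molecular configurations/trajectories** (GRO, XYZ, or a simple CSV
  dialect) — radial distribution functions g(r) between Ca²⁺ and
  candidate coordinating atoms, distance-threshold contact detection
  (default 0.4 nm to the carboxylate carbon), the stoichiometry spectrum
  of one ion coordinating *i* carboxylates (and the converse), the
  fraction of frames in which every ion is engaged in salt bridges, and
  Shrake–Rupley solvent-accessible surface area (SASA, probe 0.14 nm) as
  an oligomerization readout;

plus a **counterion-bridging Monte Carlo** that reproduces the biphasic
cluster-size-vs-concentration curve from three ingredients (ion–site
binding, an ion-bridge reward, and charge repulsion between
neighbouring particle complexes), **sequence charge bookkeeping** (formal
charges at pH 7.4, e.g. the SNAP25B reference: 206 aa, 43 negative, 30
positive; its SNARE-motif peptide 35–64 has net side-chain charge −6),
and **seeded synthetic-data generators** that make every stage testable
with known ground truth.

## Worked example

Generate a synthetic membrane-sheet image with 40 % of its signal in
clusters, then measure it:

```python
import numpy as np
import ionbridge as ib
from ionbridge.synthetic import ImageSpec, gen_sheet_image
from ionbridge.imaging import SheetImage, ROI

spec = ImageSpec(width_px=128, height_px=128, pixel_size_nm=65.0,
                 cluster_density_per_um2=1.0, cluster_radius_nm=80.0,
                 clustered_fraction=0.4, seed=7)
img, truth = gen_sheet_image(spec)
sheet = SheetImage(img, spec.pixel_size_nm)
roi = ROI(0, 0, 128, 128)

rel_sd = ib.relative_sd(sheet, roi, background=spec.background_level)
maxima, density = ib.detect_clusters(sheet, roi, noise_level=5.0)
curve = ib.autocorr_curve(sheet, roi, max_shift_px=8)
radius = ib.radius_from_autocorr(curve, poly_order=4)
print(f"rel. SD          {rel_sd:.3f}")
print(f"cluster density  {density:.2f} per um^2   (generated: 1.0)")
print(f"cluster radius   {radius:.0f} nm          (half-decay of sigma=80 nm: 133 nm)")
```

prints

```
rel. SD          1.398
cluster density  1.04 per um^2   (generated: 1.0)
cluster radius   134 nm          (half-decay of sigma=80 nm: 133 nm)
```

The rel. SD is dimensionless and rises with the clustered fraction; the
recovered radius estimates the 50 %-decay of the autocorrelation, which
for Gaussian clusters of width σ is 2√(ln 2)·σ ≈ 1.665 σ.

On the trajectory side, a fixture with known contact stoichiometry
round-trips through the full analysis:

```python
from ionbridge.synthetic import BridgedFrameSpec, gen_bridged_frames

spec = BridgedFrameSpec(n_ions=3, n_sites=30,
                        contact_distribution={1: 0.5, 3: 0.5},
                        n_frames=2000, seed=1)
traj, truth = gen_bridged_frames(spec)
spectrum = ib.stoichiometry_spectrum(traj, threshold_nm=spec.contact_radius_nm)
print(spectrum.ion_with_i_sites)       # {1: 1.515, 3: 1.485}
print(ib.bridging_frame_fraction(traj, threshold_nm=spec.contact_radius_nm))  # 1.0
```

The measured spectrum equals the generator's realized ground truth
exactly and sits within sampling error of the nominal {1: 1.5, 3: 1.5}
ions per frame.

The Monte-Carlo demonstrator:

```python
from ionbridge.mc import biphasic_scan
rows = biphasic_scan(seed=0)        # reference parameters, ion counts 6/96/3000
print([round(r["mean_cluster"], 2) for r in rows])   # [1.04, 2.57, 1.4]
```

— mean cluster size peaks at the intermediate ion count and collapses at
both extremes, the biphasic signature.

There is also a CLI (`ionbridge simulate|image|traj|mc|charge ...`); run
`ionbridge --help`.

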