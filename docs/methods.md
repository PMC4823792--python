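# Methods

`ionbridge` analyses ion-induced clustering of anionic membrane proteins
from two directions — fluorescence images of membrane sheets and
molecular configurations — and ships a Monte-Carlo demonstrator of the
counterion-bridging mechanism plus seeded synthetic-data generators. This
note records the models, the defaults and why, the numerical choices, and
the limits of what the synthetic fixtures can show.

## Image arm

**Unit of analysis.** A `SheetImage` is a 2-D non-negative intensity
raster with a pixel size in nm; regions of interest (ROIs) are axis-aligned
rectangles in 0-based pixel coordinates (origin top-left). Areas are
`width × height × pixel_size²`.

**Background-corrected mean.** Mean ROI intensity minus the mean of a
background ROI placed off the sheet. Negative results are returned rather
than clamped; they flag a bad ROI choice.

**Relative standard deviation (rel. SD).** The coefficient of variation
of background-corrected ROI pixels: population SD divided by the mean. It
is zero for a perfectly uniform stain and grows as signal concentrates in
microdomains, because both peaks and valleys contribute deviations from
the mean. It is invariant under multiplication of all intensities (so it
does not depend on illumination or gain) but not under addition, which is
why background must be subtracted first. Normalisation to a control
condition is a separate, explicit step (`normalize_to_control`) so that
per-day baselines can be factored out the way multi-day experiments are
usually pooled. The metric is undefined when the corrected mean is not
positive; this raises rather than returning a sentinel.

**Cluster counting.** `find_maxima` follows the ImageJ "find maxima"
contract: a candidate regional maximum (an equal-valued plateau with no
higher neighbour and at least one lower one, 8-connected) is counted if it
cannot be reached from higher terrain without descending more than the
user's noise level. Implementation: process plateaus in descending value;
flood the connected region strictly above `value − noise_level`; absorb
any lower maxima inside the flood; discard the candidate if the flood
touches a higher pixel. Plateau centroids are reported. The noise level is
a required argument — the workflow this mirrors applies one fixed noise
level to all recordings of a dataset, and no universal default exists.
Counts divided by the ROI area give the cluster density per µm².

**Autocorrelation radius.** The ROI is correlated (Pearson) with a copy
shifted rightward pixel by pixel, on the overlapping region only; curves
from several ROIs are averaged pointwise; a polynomial (default order 4)
is least-squares fitted and the shift at which the fit first crosses the
midpoint between its value at shift 0 and its baseline — the fitted value
at the largest shift, since the reference level is otherwise undefined —
is the 50 %-decay radius. For a Gaussian object of width σ the image
autocorrelation is Gaussian of width σ√2, so the half-decay radius is
2√(ln 2)·σ ≈ 1.665 σ; recovery tests use this closed form as ground
truth. The fit range matters: the default tests use a maximum shift of
about four times the object σ in pixels; fitting far into the flat tail
biases the polynomial and the crossing downward. An isotropic variant
(averaging horizontal and vertical shifts) exists but is off by default,
matching the rightward-shift convention.

**Punctate signal fraction.** Pixels above `mean + k·SD` of the
background-corrected ROI (default k = 2) are segmented as puncta; the
fraction of total signal inside them is reported. k = 2 is a conventional
threshold for "bright" pixels under near-Gaussian backgrounds; the
measured fraction underestimates the generative clustered fraction (cores
only) but is monotone in it, which is the property used downstream.

## Trajectory arm

**Containers and formats.** A `Trajectory` is an atom table (pandas)
plus `(frames, atoms, 3)` coordinates in nm and a per-frame orthorhombic
box; triclinic boxes are rejected. Readers: GRO (fixed columns, nm,
multi-model files; parse errors carry line numbers, a missing box line is
an explicit error), XYZ (nm, optional `box=` token) and an internal CSV
dialect (`frame,atom_id,role,x,y,z` with the box on a comment line). Atom
roles (carboxylate carbons of Asp/Glu/C-terminus, backbone oxygens, Gln
carbonyl oxygen, Ser/Thr hydroxyl oxygens, amino nitrogens, and the
monatomic ions) are pure functions of residue name, atom name and a
C-terminal flag inferred from the presence of OXT/OC1/OC2.

**Distances.** All pair distances use the minimum-image convention in the
orthorhombic box.

**RDF.** `g(r)` is the pair-distance histogram normalised by shell
volume, frame count, reference-group size and the partner density
`n_b / V`; self-pairs are excluded when the groups coincide. Default bins:
0.002 nm up to 1.0 nm. `first_shell_threshold` smooths g(r) with a 3-bin
moving average, finds the first maximum above 1 and returns the first
subsequent local minimum with g < 1 (an inter-peak dip inside a bimodal
first shell stays above 1 and is skipped; the shell boundary falls below
it). Featureless RDFs fall back to the per-role threshold table with a
warning; the carboxylate default is 0.40 nm, the only per-role value that
is certain, with the other roles spanning the 0.25–0.5 nm first-shell
range typical of Ca²⁺ partners.

**Contacts and stoichiometry.** A contact is an ion–site pair within the
threshold (default 0.4 nm, measured to the carboxylate carbon, as the RDF
is defined on carboxylate carbons; an oxygen mode is available). Per
frame, ions with exactly *i* site contacts (i = 1..10) and sites with
exactly *i* ions (i = 1..3) are tallied and divided by the number of
analysed frames; zero-contact ions and sites are excluded from the spectra
but reported separately, so either normalisation convention can be
reconstructed. The analysis window defaults to the trailing 20 % of
frames, generalising a "last 20 ns of 100 ns" averaging convention.
`bridging_frame_fraction` is the fraction of window frames in which every
ion has at least `min_sites` contacts; `min_sites=1` is the "all ions in
salt bridges" reading and `min_sites=2` the "all ions bridging several
carboxylates" reading — both are reported by the pipeline.

**SASA.** Shrake–Rupley with a deterministic golden-section spiral of
test points (default 960) on each atom's sphere inflated by the probe
radius (default 0.14 nm, water-sized). A point is accessible if outside
every neighbour's inflated sphere; neighbours include periodic images
when a box is present. Van der Waals radii come from a bundled Bondi
table with a per-call override. Ions are excluded as occluders by default
(flag to include). Window statistics are means ± s.e.m. over frames
within a run; across runs the s.e.m. is taken across run means (n = number
of runs), matching multi-copy simulation conventions. Determinism: for a
fixed point count the algorithm has no randomness; rotation invariance
holds to ~0.5 % at 960 points (the point lattice is not rotation
invariant), and periodic wrapping of coordinates changes nothing.

## Counterion-bridging Monte Carlo

A deliberately minimal, lattice-free 2-D model (the membrane plane) of
the proposed mechanism, not a fit to any measured system. Particles carry
`S` unit-negative sites (default 6, a small-peptide-scale carboxylate
count); divalent ions can hold up to 4 sites (coordination of several
carboxylates by one ion) but only while within the contact radius of the
owning particle.

Energy (units of kT):

* binding: `bind_energy + binding_entropy` per ion–site bond. The
  entropy term (+2 by default, against −1 of contact energy) is the cost
  of confining a free ion to a site, so that a lone bond is marginally
  unfavourable and site occupancy is driven by the local free-ion
  availability — the model's stand-in for concentration.
* bridging: `bridge_energy` (−2.25) per extra particle linked by one
  ion. This is the clustering ingredient.
* charge repulsion: each particle's net charge is
  `q = −S + Σ 2/k_ion` (a bound ion splits its +2 among the `k` distinct
  particles it holds); particle pairs closer than `repulsion_range_nm`
  (2.4 = twice the contact radius) contribute `0.25 · q·q'`. This
  screened-Coulomb-like contact term is the dispersal ingredient: bare
  particles (q = −6) repel, neutralised ones do not, overcharged ones
  repel again.

The three regimes follow: scarce ions → bare, mutually repelling
particles stay a gas; intermediate counts (~4 ions per particle in the
box) → bound ions neutralise the particles and bridges assemble
oligomers; large excess (~3000 ions in the 20×20 nm box) → the local
free-ion density makes one-ion-per-site occupancy entropically dominant,
bridges are outcompeted, particles overcharge and re-disperse. The
reference scan (6 / 96 / 3000 ions, 24 particles, 800 sweeps, 4 seeds)
yields a biphasic mean-cluster-size curve with the middle count exceeding
both extremes (one-sided Welch t, α = 0.05).

Sampling: Metropolis over particle translations (accepted on the change
in the charge-pair energy, gated by bound-ion tether constraints and an
optional hard core), ion translations (unbound ions move freely), and
bind/unbind toggles. A toggle draws a site uniformly and then an ion
uniformly among those within contact range of the owning particle; that
candidate set depends only on positions, which toggles never change, so
the proposal is exactly symmetric and detailed balance holds — verified
against exact Boltzmann enumeration of a frozen two-particle/one-ion
system. The running energy is updated incrementally and must agree with a
full recomputation to 1e-9 kT at the end of every run. Cluster readout:
union-find over "particles sharing a bound ion" (optionally also direct
proximity); observables are mean and largest component size, averaged
over the trailing half of sweeps.

Model properties worth knowing. (i) An ion bound to two particles is a
geometric tether even when `bridge_energy = 0`, so the fully nulled model
(no bridge reward, no charge term) still shows residual association at
intermediate counts; the clean "no clustering anywhere" ablation is
bridging removal with the charge term retained. (ii) Without the charge
term, the high-ion regime equilibrates very slowly (bridges must be
displaced one by one through uphill states); short scans there understate
the equilibrium cluster size, which long single runs show to keep
growing. The ablation test therefore asserts that removing the charge
term keeps the high end clustered rather than asserting a strict
monotone shape at fixed sweep counts. (iii) Ion count proxies
concentration in a fixed box; no quantitative mapping to mM is claimed.

## Sequence charge bookkeeping

Integer formal charges at stated pH: D, E → −1; K, R → +1; His neutral by
default (side-chain pKa ≈ 6, so <3 % protonated at pH 7.4) with an opt-in
positive convention; free termini ±1 on request. On the bundled rat
SNAP25B reference (206 aa) the neutral-His convention reproduces the
published counts (43 negative, 30 positive; the sequence has exactly one
His), and the SNARE-motif peptide spanning residues 35–64 (30 aa,
Leu…Met) has net side-chain charge −6. The bundled ion property table
(charge, Shannon crystal radius, Jones–Dole viscosity B, Marcus hydration
free energy, representative coordination number) is versioned data with a
source column; `charge_to_radius` is the charge / crystal-radius ratio in
e/Å used to order cations by clustering efficacy.

## Synthetic data generators

All generators draw from a single `numpy.random.default_rng(seed)` per
call and are byte-reproducible.

* **Sheet images.** Uniform background + diffuse signal + Poisson-placed
  clusters. Clusters are 2-D Gaussians with σ = `cluster_radius_nm`,
  truncated at 3σ and normalised so each carries an equal share of the
  clustered signal; `clustered_fraction` fixes the expected clustered
  share of the specific signal before noise, and the realized split is
  returned as ground truth. Optional Gaussian PSF blur uses wrap mode so
  total intensity is conserved exactly; noise is Gaussian or Poisson
  (with photon gain, default 1). Defaults (128², 65 nm pixels, 4 µm⁻²
  clusters of 80 nm, 30 % clustered) are chosen for testability — the
  real microdomain density/size priors are unknown — so tests that pass
  on these fixtures validate the estimators' arithmetic and monotonicity,
  not biological realism: no vignetting, no chromatic effects, no
  structured background, no label stochasticity.
* **Ideal-gas frames.** I.i.d. uniform positions in a periodic box; the
  RDF calibration fixture (g ≡ 1).
* **Bridged frames.** Per frame and ion a contact count is drawn from
  the user distribution; exactly that many sites are placed inside 90 %
  of the contact radius around the ion and all remaining sites beyond
  radius + margin of every ion, with ions spread at least two outer radii
  apart so shells cannot interact. Placement retries are capped (default
  1000); failure raises an error naming the frame. The realized (not
  nominal) spectrum is returned as ground truth, and brute-force distance
  recomputation confirms the construction in every frame. These frames
  are statistical, not physical: no dynamics, no excluded volume, no
  solvent.

## Numerical choices and degenerate inputs

Polynomial fit order 4 by default (configurable); NaN PCC values
(zero-variance overlaps) are excluded pointwise from curve averages; a
non-decaying fitted curve raises. RDF `r_max` must not exceed half the
smallest box edge. Empty ROIs, unknown residues (with position), missing
van der Waals radii (with atom names), infeasible placements (with frame
index) and missing boxes all raise typed errors rather than degrading
silently. CLI exit codes: 0 success, 1 usage error, 2 data error.

## Problem sizes used in tests and the acceptance script

Ideal-gas RDF: 1000 particles × 100 frames. Stoichiometry recovery: 3
ions, 30 sites, 2000 frames. Radius recovery: 20 seeds of 128² images.
SASA oracles: 960 sphere points, 2×10⁵-point MC surface integration.
Monte Carlo: 24 particles, 800–2000 sweeps, 3–4 seeds per ion count.
These sizes give the statistical resolution the assertions need (3·SE
bands, 2 % geometric tolerances) at desk scale.

## Known limitations

The image estimators assume isotropic, roughly Gaussian cluster profiles;
rel. SD conflates cluster size, density and sorting changes (by design —
it is the segmentation-free summary). The trajectory arm analyses given
configurations; it performs no simulation and no hydrogen-bond analysis,
and the published headline trajectory numbers (bridging-frame
percentages, SASA curves of specific runs) are not reproducible without
the original trajectories. The Monte Carlo is a mechanism demonstrator:
its parameters are effective, its ion count is not a molar concentration,
and no numeric agreement with any measured system is claimed.
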