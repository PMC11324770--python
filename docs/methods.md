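# Methods

`occlusim` models an imaging-based surrogate assay for lung epithelial
barrier integrity and the pharmacokinetic context needed to interpret it:
a confluent alveolar epithelial monolayer is stained for nuclei, whole-cell
body and the tight-junction protein occludin; the occludin area localized
to cell–cell membranes, normalized per cell and to vehicle control, falls
with increasing compound concentration; an IC50 summarizes the potency of
that fall; and a generation-resolved lung PBPK model translates an inhaled
dose into regional epithelial-lining-fluid (ELF) exposure that can be read
off the in vitro dose–response curve.

## Synthetic monolayer fields (`synthimg`)

**Geometry.** Nucleus centers are rejection-sampled uniformly with a
minimum pairwise separation of twice the nucleus radius (default 5 px →
10 px separation); cells are the Voronoi tessellation of the centers,
computed by nearest-center assignment over the pixel grid. This produces
the polygonal "cobblestone" appearance of a confluent epithelial monolayer
at O(n log n) cost. The membrane skeleton marks, for each pair of
4-adjacent pixels with different labels, the upper/left pixel — a 1-px
inter-cell boundary with no boundary at the image border.

**Channels.** The nuclear channel holds Gaussian blobs (σ = radius/2.5,
chosen so that thresholded nuclei remain disjoint at the minimum center
separation). The whole-cell channel is a uniform cytoplasm level with the
membrane rendered as an intensity *dip* along the skeleton — whole-cell
dyes stain membranes weakly, which is exactly why the quantification
pipeline inverts this channel. The junction channel carries signal on a
subset of the skeleton dilated by 1 px. Additive Gaussian noise
(default SD 20 on a 16-bit scale) is applied last and clipped at zero;
shot noise, uneven illumination and PSF blur are deliberately not
modelled (see Limitations).

**Junction dropout.** Treatment effect is segment-wise: whole shared
cell–cell edges are randomly selected until the chosen skeleton length
reaches the target integrity fraction, with the final edge truncated to
hit the target. Degraded epithelium therefore shows contiguous junction
gaps rather than pixel-wise salt-and-pepper loss.

**Plates.** A default single-compound plate carries a 9-point 1:3 serial
dilution from 100 µM (lowest point 15.2 nM) in duplicate wells plus two
vehicle wells; 16 fields are imaged per well. Under treatment at
concentration c the generated integrity is 1/(1+(c/IC50)^h) and the
cytotoxic cell-loss fraction 1 − 1/(1+(c/EC50)^h) (no loss unless a
viability EC50 is given). Per-field seeds derive from the master seed and
the (plate, well, field) coordinates through a `SeedSequence`, so any
field is regenerable in isolation and full runs are bit-reproducible.

**Defaults.** 256×256 px fields, 64 cells/field, 0.325 µm/px (a typical
40× widefield sampling; always configurable and recorded in outputs).
Intensity levels (background 100, cytoplasm 1000, membrane dip 600,
junction 2000, nucleus 3000) put all channels comfortably inside the
16-bit range with strong but not extreme contrast.

## Quantification (`quantify`)

1. **Nuclei**: Gaussian smooth (σ = 2 px) → Otsu threshold → area filter →
   distance-transform local-maxima watershed with a minimum peak
   separation (7 px) to split touching nuclei; the count is the viability
   readout.
2. **Membranes**: the whole-cell channel is inverted (max − value) so
   membranes become ridges, then flooded by a marker-controlled watershed
   seeded at the nucleus centroids. Centroid (not whole-blob) seeding
   matters: a nucleus lying against a cell edge can otherwise spill its
   marker across the 1-px ridge. Boundaries between watershed labels give
   the 1-px membrane outline (4-connectivity; image-border boundaries
   excluded by default since only inter-cell membrane carries tight
   junctions — a config flag includes them).
3. **Band growth**: the outline is dilated with a Euclidean disk of radius
   10 px ("10 px on either side"), giving a 21-px-thick band along straight
   membrane stretches. The radius-10 digital disk contains exactly the 317
   lattice offsets with dx²+dy² ≤ 100.
4. **Junction**: the junction channel is thresholded directly (its
   staining is specific enough that no inversion is needed), despeckled,
   skeletonized to 1-px curves and grown by the same disk. A
   threshold-then-dilate variant is available behind a config switch.
5. **Areas**: membrane area = thresholded whole-cell staining inside the
   membrane band; junction-at-membrane area = thresholded junction
   *staining* inside the overlay of the thickened junction mask and the
   membrane band. Counting the staining area within the overlay — rather
   than the overlay area itself — keeps the endpoint proportional to the
   true junction length; the thickened-mask area alone decays sublinearly
   because dilated segments bleed into small gaps. Areas are totalled over
   the whole image and converted with the pixel size (µm²).
6. **Per well**: areas and nuclei counts are averaged over the fields of a
   well and per-cell values formed as ratio of means (mean area / mean
   count), which is robust when single fields hold few cells; a
   mean-of-ratios convention is available by config. A zero mean count
   flags per-cell values as undefined instead of silently emitting NaN.

All thresholds are Otsu per channel per field, making every mask invariant
to a global intensity rescaling. Coordinates are (row, col) and 0-based;
boundary tests use 4-connectivity and connected components 8-connectivity,
stated so geometry tests are bit-exact.

## Dose–response (`doseresponse`)

Responses are fold changes over the same-plate vehicle mean of junction
area per cell; nuclei-count fold change is carried in parallel as the
viability endpoint and never mixed into the junction endpoint. Replicate
wells at one concentration are averaged within a plate; biological
replicate plates contribute independent response sets and fits pool all
points.

**IC50.** The default estimator regresses response on
log10(concentration) over the points bracketing the 0.5 crossing (minimum
three points; if the local regression leaves the bracketing interval on
non-monotone data, the crossing is interpolated between the bracketing
pair and the fit flagged) and solves for the concentration at response
0.5. A 4-parameter logistic (top free near 1, bottom in [0, 0.5]) is
available as `method="fourpl"`. An IC50 is **established** only when the
normalized response reaches ≤ 0.5 somewhere inside the tested range; this
single rule reproduces the typical screening pattern where compounds with
only minor effects at the top concentration report no curve. When several
crossings exist, the lowest-concentration crossing is used and flagged.
Established IC50s are reported within the tested range. Classification is
POSITIVE iff established.

**Predictivity.** Cooper statistics: sensitivity TP/(TP+FN), specificity
TN/(TN+FP), accuracy (TP+TN)/N, with empty classes reported as undefined
rather than 0/0. Per-concentration group comparisons use the textbook
pooled-variance two-sample Student's t (two-sided; p from the t
distribution with n1+n2−2 df); no multiplicity adjustment is applied
across the nine concentrations and the output says so.

## Lung PBPK (`lungpbpk`)

The lung is discretized into 24 airway generations (1 = trachea; 1–16
tracheobronchial, 17–24 alveolar) plus an extra-thoracic sink, each
generation holding ELF, epithelium and sub-epithelium compartments and a
volume-less "deep" binding compartment on each tissue. The flux contract
per generation:

- **Dissolution** (solid formulations) by the Nernst–Brunner law,
  rate = (D/h)·A(m)·(Cs − C_ELF), with A(m) the surface of n monodisperse
  shrinking spheres at the current undissolved mass. Supersaturation is
  clipped to zero rate (no precipitation modelling; flagged as a model
  assumption). Particle number per generation is fixed at deposition;
  solid moved by mucociliary transport dissolves with the receiving
  generation's size coefficient, and a generation that received no
  initial deposit passes solid through undissolved — conservative for
  lung exposure.
- **Mucociliary clearance**: first-order transfer of total ELF content
  (dissolved + solid) toward the trachea, zero in alveolar generations;
  the trachea clears into a swallowed sink from which nothing is
  reabsorbed (again conservative for lung exposure).
- **Permeability**: bidirectional ELF↔epithelium flux P·SA·(C_ELF −
  fu·C_epi) with no non-specific ELF binding (ELF unbound = total);
  alveolar permeability defaults to 10× the tracheobronchial value.
- **Tissue exchange**: diffusion-like first-order epithelium↔
  sub-epithelium exchange on unbound concentrations (rate constant
  `k_epi_sub_per_h`, default 10/h, times the epithelium volume as the
  exchange "PS").
- **Perfusion**: perfusion-rate-limited sub-epithelium↔blood exchange
  Q·(C_plasma − C_sub/Kp); tracheobronchial generations share the
  bronchial blood flow and alveolar generations the cardiac output, both
  distributed as constant flow per tissue volume.
- **Systemic**: one-compartment plasma with clearance CL and volume Vss.

Units are nmol, µM (nmol/ml), ml, cm², hours. Every flux appears with
opposite signs in exactly two state derivatives, so mass is conserved by
construction; integration uses LSODA at rtol 1e-8 and the run aborts if
the worst relative mass-balance residual reaches 1e-6 or any state goes
meaningfully negative.

**Morphometry.** The default 24-generation table is a scalable
Weibel-like parameterization (airway count doubling per generation,
geometrically shrinking tracheobronchial calibre/length, alveolar surface
area ~4000 cm² dwarfing the ~50 cm² tracheobronchial surface, ELF
thickness 10→2 µm down the tracheobronchial tree and 0.2 µm in alveoli,
mucociliary rate decaying distally and zero in alveoli, rat-scale cardiac
output 4.8 L/h with 1% bronchial flow). These are structural defaults
chosen to reproduce the qualitative regional exposure gradient, not a
fitted anatomical dataset; every value is overridable from CSV.

**Exposure mapping.** Regional ELF concentration is the ELF-volume-
weighted mean over member generations (upper TB 1–6, lower TB 7–16,
alveolar 17–24); Cmax is its maximum over time. Each region's Cmax is
joined to the in vitro curve as an exposure ratio Cmax/IC50 and a
predicted fold-change response; a region is flagged at-risk when Cmax
reaches a configurable fraction of the IC50 (default 0.5, the regime in
which observed airway pathology has coincided with near-IC50 ELF
exposure).

## What the synthetic data does and does not show

The generator reproduces the geometry and contrast relationships the
algorithm depends on (cobblestone tessellation, dim membrane ridges,
junction-specific staining, dose-dependent segment dropout, cytotoxic
nucleus loss) with known ground truth, so passing tests demonstrate that
the measurement chain — segmentation, band geometry, normalization, IC50
estimation — is correct and unbiased under those assumptions. It does not
emulate optical PSF, shading, multilayer growth, staining variability or
instrument noise statistics, so the tests bound algorithmic error, not
the biological or optical error of a real screen.

## Numerical choices and degenerate inputs

- Otsu on a constant image is undefined; such channels yield empty masks
  and a nuclei count of 0 (not an error).
- Watershed ties on noiseless plateaus are broken by flooding order; the
  outline can locally deviate from the true skeleton near shallow-angle
  stair runs (observed ≤ 2 px) while two-cell fields stay within 1 px
  Hausdorff and label agreement stays ≥ 99%.
- 16-bit TIFF export rounds intensities to the nearest integer and raises
  on values above 65535 rather than clipping silently.
- IC50 fits require ≥ 4 distinct concentrations; zero pooled variance in
  the t test reports p = 0 (or 1 for identical means) with a flag.
- ODE output is checked, not trusted: negative states and mass-balance
  violations raise with diagnostics.

## Problem sizes used in the shipped checks

The parameter-recovery check simulates the full study design (3 replicate
plates × (9 concentrations in duplicate + 2 vehicle wells) × 16 fields of
256×256 px at 64 cells/field) for each of six potency/slope combinations;
the demonstration workflow defaults to a reduced 2–4 fields/well plate so
a complete run stays interactive. Segmentation oracles use 50-cell
noiseless fields; PBPK checks run the 24-generation model over 12–24 h
horizons.

## Known limitations

- The PBPK module consumes given parameters; it does not estimate them
  from in vivo PK, and its default morphometry/compound values are
  structural placeholders, so absolute ELF concentrations are not
  comparable to any particular published study — the regional *pattern*
  and the conservation/limit laws are the tested claims.
- Plasma is one-compartment; no enterohepatic or oral reabsorption of
  swallowed drug.
- The imaging assay is 2D; phenomena requiring 3D culture (multilayering,
  dome formation) are out of scope.
- The establishment rule is a single fixed threshold (response ≤ 0.5 in
  range); alternative hit-calling rules are not implemented.
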