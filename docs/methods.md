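# Methods

This note documents the models, estimators and numerical choices behind
`lipidring`, in the package's own terms.

## Coordinate model and units

Everything internal is nm and ns. The membrane plane is xy and periodic
(minimum-image in x and y only); the membrane normal z is open — the
analyses are membrane-planar, so the simulation engine's full 3D periodicity
is deliberately not modelled. Boxes are orthorhombic. Ångström appears only
at format boundaries (DCD files, the 5 Å density-grid convention) and in
reported depression depths.

## Synthetic membrane generator

The generator stands in for a microsecond coarse-grained simulation of a
POPC/POPE/cardiolipin bilayer around a prohibitin ring. It is a *statistical*
emulator: it reproduces the distributional features the analyses measure,
not the force-field physics.

**System definition.** The `paper_scale` preset builds the published
composition — upper leaflet 900 POPC / 700 POPE / 400 cardiolipin, lower
leaflet 918 / 720 / 420 — with one phosphate bead per POPC/POPE and two per
cardiolipin (one per negative charge), 0.5 nm apart laterally. Leaflet
phosphate planes sit at z = ±2 nm (4 nm thickness). Schedule: 4000 frames at
1 ns, i.e. 4 μs of sampled output. The `desk` preset scales the composition
by 1/10 (rounding the lower leaflet up: 90/70/40 and 92/72/42) and runs 200
frames; it is the configuration used throughout the test suite, chosen so a
full pipeline run takes ~2 s while keeping enough molecules for
distributional tests.

**Ring.** 22 subunits alternating PHB1/PHB2 on a 10 nm circle at the box
centre (36 × 36 nm box). The real ring's subunit count and radius are not
established; these defaults give a ring that fits the stated lipid count at
a physiological area per lipid (~0.63 nm²) and are fully configurable. Each
subunit carries only its membrane-facing key residues — basic PHB1 K4, R41,
K63 and PHB2 K6, R17, R54, R71; polar PHB1 H55 and PHB2 Y34, G35, S39, Y77 —
as one backbone bead plus (for non-glycine) one sidechain bead jittered
0.15 nm around the subunit anchor at mid-membrane height.

**Dynamics.** Per frame each free lipid takes an overdamped-Langevin lateral
step √(2 D Δt)·N(0,1) per axis, D = 0.1 nm²/ns for all species by default (a
typical coarse-grained lipid magnitude; it sets the variance of the
statistical tests, not their expectations). Cardiolipin additionally drifts
down the gradient of an attraction well

    U(d)/kT = −ε · exp(−(d − R)² / 2σ²)

centred on the ring circle (d = lateral distance to the ring centre,
R = ring radius; a flag recentres the well on the disk centre). Defaults
ε = 4 kT, σ = 2 nm — a well a few lipid diameters wide, deep enough that
sorting is obvious within a desk-scale run. The drift displacement is
−D Δt ∇U/kT, so the stationary density tends to the Boltzmann profile.
Lipids have no excluded volume: the analyses under test are statistical and
hard-core repulsion would add cost without changing any measured
expectation.

z is not integrated: each frame draws fresh Gaussian noise (σ_z = 0.1 nm)
about the leaflet base, minus the invagination surface

    h(d, t) = A(t) · exp(−d² / 2w²),

applied downward to *both* leaflets (the membrane moves as a sheet) and to
the otherwise static protein beads. A(t) ramps linearly from 0 to A_max over
`ramp`·n_frames frames, clamped so the final frame is exactly A_max.
Defaults A_max = 0.7 nm and w = 5 nm (half the ring radius): a 7 Å
depression, the scale reported for this system.

A `bound_fraction` of cardiolipin can be tethered: each tethered molecule is
re-placed every frame at `bound_distance` (default 0.5 nm) from its randomly
assigned residue reference bead, with isotropic angular jitter. This
produces the sharp pair-correlation peak at the binding distance and
near-unit interaction frequencies that a physically bound lipid would. The
default is 0 — tethering is switched on explicitly by analyses that study
bound populations.

Every run is driven by one `numpy` Generator seeded from `seed`; identical
(parameters, seed) gives bit-identical trajectories. The ground-truth
manifest records the per-lipid leaflet (constant — no flip-flop), the
tethered molecules, the per-frame in-ring cardiolipin fraction and the
per-frame amplitude.

**What the generator does not emulate** — and hence what passing tests do
not show about real membranes: force-field energetics, lipid–lipid
correlations and excluded volume, membrane undulations beyond the imposed
Gaussian, protein flexibility, leaflet flip-flop, and curvature–composition
coupling. Tests against the generator validate the *estimators* (their
conventions, normalizations and conservation laws), not membrane physics.

## Leaflet assignment

A lipid is labelled by comparing its first phosphate bead's z with the local
midplane: the mean phosphate z of all lipids within a 3 nm lateral radius
(periodic xy). The local rule keeps invaginated membranes correctly split
where a global threshold would fail. The global mean z is used instead when
the neighborhood is uninformative: fewer than 10 lipids, or a z spread under
2 nm — a neighborhood drawn from a single leaflet contains no midplane
information, and its mean would sit on the lipid itself (this degenerate
case occurs at low desk-scale densities). Ties keep the previous frame's
label, and go to "upper" at frame 0, making the assignment deterministic.
Cardiolipin's second phosphate bead always inherits the first bead's label.
The mapping of generated leaflets to membrane-biology vocabulary (upper =
outer) is a documented convention, not a computation.

## Radial distribution function

The continuum definition (δ-function over pair distances, 4πr² shell
measure, local-density normalization over spheres of r_max = 1.5 nm around
the A beads) is estimated with distance bins: for bin k,

    g_k = C_k / (n_frames · N_A · V_shell(k) · ⟨ρ_B⟩_local),

with C_k the raw pair count and ⟨ρ_B⟩_local the joint mean over frames and
A beads of (B within r_max) / ((4/3)π r_max³). A pair at distance d enters
bin ⌊d/Δr⌋ when d ≤ r_max and the index is within range. Numerical
choices:

* Δr defaults to 0.02 nm (unstated in the source analyses; fine enough to
  localize a 0.5 nm peak to one bin).
* `exact_shell` volumes (4π/3)(r³₊ − r³) by default; the `midpoint_4pir2`
  flag reproduces the literal 4π r_mid² Δr reading. The difference is
  O((Δr/r)²) and matters only in the first bins.
* ⟨ρ_B⟩_local is averaged jointly over frames and A beads; a `per_frame`
  mode normalizes each frame by its own local density first. Which averaging
  the original analysis used is not documented; joint averaging is the
  default because it keeps g exactly reconstructable from the stored raw
  counts.
* Both cardiolipin phosphate beads count as independent B particles
  (`cl_single_bead` collapses to one per molecule).
* The 3D spherical normalization is kept even though the geometry is a
  quasi-planar slab, so g does **not** tend to 1 at large r; with the local
  (not box-wide) reference density, values remain comparable across residues
  and species, which is what the analysis uses them for.

Pair search uses a kd-tree with periodic boxsize, the z axis lifted onto a
period large enough that it can never wrap within r_max; exact distances are
recomputed with the package's own minimum-image function so boundary
behaviour is identical to the brute-force definition (this equivalence is
tested exactly, count for count).

## Density maps and windows

Phosphate beads are binned into half-open square cells (default 0.5 nm)
anchored at the box origin; a bead exactly on a boundary belongs to the
higher-index cell. Counts are averaged per frame over the window, so the
grid sums exactly to the mean per-frame bead count (asserted, not assumed);
per-area density divides by the cell area. Window presets take the first and
last 2.5% of frames (at full scale: 0–0.1 μs and 3.9–4.0 μs), minimum one
frame; windows are explicit everywhere because single-frame maps at desk
scale are mostly shot noise.

## Contacts and interaction frequency

A residue instance (residue × subunit) is in contact in a sampled frame when
any cardiolipin phosphate bead — the headgroup representation of the
two-charge model — lies within 0.6 nm of the residue's reference bead.
Frames are sampled at 1 ns. Frequency = contact frames / sampled frames.
Leaflet resolution attributes a contact to the contacting molecule's current
leaflet label; a frame with contacts from both leaflets counts once toward
the total (union) and once per leaflet, so the total stays in [0, 1] and
bounds each per-leaflet frequency. The residue-class distance profile
(basic/polar/acidic/nonpolar vs minimum distance to the chosen leaflet's
headgroup plane) uses 0.1 nm bins over 0–1.5 nm, frame-averaged.

## Ring region, enrichment, depression

The ring region is the disk from an algebraic (Kåsa) least-squares circle
fit to the protein beads' xy positions — solving [2x 2y 1]·[a b c]ᵀ = x²+y²
— assuming the ring does not straddle the periodic boundary. In-region
counts use each molecule's first phosphate bead and periodic lateral
distance. The enrichment ratio (in-region areal density over leaflet-wide
areal density) is 1 in expectation under uniform placement; with 82
cardiolipins per desk run and a region covering 24% of the box, a single
seed's time-averaged ratio carries an irreducible ±0.15-ish spread from
placement noise, so single-seed point checks of "ratio = 1" are
underpowered at desk scale — the tests therefore assert unbiasedness across
seeds and strict monotonicity in the attraction depth (which shares random
numbers across ε values).

Height fields are per-cell mean phosphate z of one leaflet over a window,
with an occupancy mask and an optional mask-aware 3×3 periodic mean filter
(off by default). The change map subtracts initial from final fields on the
mask intersection. Depression depth is defined against the *final* far field
(cells beyond 1.5× ring radius) so global z drift cancels; in-ring
statistics are taken over the central half-radius disk, and both the
mean-based depth and the peak (minimum-cell) depth are reported because a
quoted depression range plausibly spans mean-to-peak. With the default
A_max = 0.7 nm and w = 5 nm the estimator reads back ≈5.5 Å mean and ≈8 Å
peak, matching the closed-form disk average of the Gaussian
(2w²/r₀²)(1 − e^(−r₀²/2w²)) minus the far-field mean.

## Pipeline and reproducibility

A strict YAML config (unknown keys are errors with nearest-key suggestions;
invalid values fail naming the full key path) drives the stages in
dependency order: generate/load → leaflets → {RDF, density, contacts,
enrichment} → curvature. All outputs are deterministic CSV/JSON listed in a
run manifest; two runs with the same config and seed are byte-identical
(manifest wall-times excluded). File formats: lossless internal JSON
(topology) and NPZ (trajectory); GRO/PDB and XTC/DCD via mdtraj for
interoperability. GRO has no chain record, so protein subunit boundaries are
recovered from residue-number resets with subunits alternating PHB1/PHB2
starting at PHB1 — the generator's own writing convention.

## Known limitations

* The generator's lipids are ideal (no excluded volume) and its z dynamics
  are memoryless noise; undulation spectra and lipid packing are out of
  scope.
* The circle fit assumes the ring does not wrap across the periodic
  boundary.
* Leaflet assignment does not handle flip-flop or closed (vesicle)
  geometries.
* Desk-scale statistics are intentionally small; quantitative one-seed
  comparisons of slowly-mixing observables (enrichment ratios, in-ring
  densities) carry placement noise that only larger systems or seed
  averaging remove.
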