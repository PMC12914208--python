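# lipidring

Leaflet-resolved lipid–protein analyses for coarse-grained membrane
trajectories containing a protein ring, plus a fully seeded synthetic
bilayer generator that provides ground truth for every analysis.

## The problem

Prohibitins (PHB1/PHB2) form large ring-shaped hetero-oligomers in the inner
mitochondrial membrane and are thought to sculpt cristae by clustering
cardiolipin — the mitochondria-specific anionic lipid carrying two phosphate
groups — underneath the ring. Coarse-grained molecular dynamics of such a
system produces microsecond trajectories of a two-leaflet POPC/POPE/
cardiolipin bilayer around a static PHB ring. Turning those trajectories into
quantitative statements requires a consistent set of estimators:

* **Radial distribution function** between protein residue reference beads
  (A) and lipid phosphate beads (B), with *local-density* normalization:

      g_AB(r) = ⟨ρ_B(r)⟩ / ⟨ρ_B⟩_local
              = (1/⟨ρ_B⟩_local) (1/N_A) Σ_{i∈A} Σ_{j∈B} δ(r_ij − r) / (4πr²)

  where ⟨ρ_B⟩_local is the density of B averaged over spheres of radius
  r_max = 1.5 nm around the A beads. The reference bead of a residue is its
  backbone bead for glycine and its (first) sidechain bead otherwise.
* **Leaflet assignment**: every lipid is labelled upper/lower per frame by
  comparing its phosphate z against a local midplane, so curved and
  invaginated membranes stay correctly split.
* **2D density maps** of phosphate beads on the membrane plane (0.5 nm =
  5 Å cells), per leaflet and species, over initial/final time windows.
* **Contact dynamics**: a residue is in contact with cardiolipin when any
  cardiolipin headgroup bead is within 0.6 nm of its reference bead, sampled
  at 1 ns intervals; the interaction frequency is the fraction of sampled
  frames in contact, resolved by leaflet.
* **Ring enrichment**: lipid counts inside the disk fitted to the ring
  (algebraic least-squares circle fit), and the enrichment ratio
  (in-region areal density) / (leaflet-wide areal density).
* **Membrane invagination**: gridded mean phosphate height fields,
  initial-to-final height-change maps, and the ring-referenced depression
  depth (far-field reference minus central-disk statistics).

Because real coarse-grained trajectories of this system are not generally
available, the package ships a Brownian lipid-sorting generator
(`lipidring.synthetic`) that reproduces the published system definition —
900/700/400 POPC/POPE/cardiolipin in the upper leaflet, 918/720/420 in the
lower, two phosphate beads per cardiolipin, 4 μs of output at 1 ns stride —
and adds controllable cardiolipin attraction toward the ring, residue
tethering, and a time-ramped Gaussian invagination, all with a ground-truth
manifest for validation.

## Worked example

```python
import lipidring as lr

# desk-scale synthetic run: 30% of cardiolipin bound 0.5 nm from ring
# residues, 0.7 nm membrane invagination under the ring
traj, truth = lr.generate("desk", seed=0,
                          overrides={"bound_fraction": 0.3,
                                     "invagination_amplitude": 0.7})
leaflets = lr.assign_leaflets(traj)

# residue-cardiolipin pair correlation
inst = lr.expand_residue_set(traj.topology, lr.ContactParams().residue_sets)
A = lr.residue_reference_beads(traj.topology, [(m, s) for m, s, _, _ in inst])
B = lr.select_beads(traj.topology, species="CL", role="phosphate")
rdf = lr.compute_rdf(traj, A, B, leaflets, lr.RDFParams())
print(f"RDF peak: {lr.peak_location(rdf):.2f} nm")

# interaction frequencies (fraction of frames in contact, 0.6 nm cutoff)
freq = lr.interaction_frequency(lr.compute_contacts(traj, leaflets))
df = freq.to_dataframe()
print(df.sort_values("frequency", ascending=False)
        .head(3)[["species", "residue_seq", "frequency"]].to_string(index=False))

# ring-referenced membrane depression
region = lr.fit_ring_region(traj.topology, traj.frame(0))
wins = lr.window_presets(traj)
dep = lr.depression_depth(
    lr.height_field(traj, leaflets, wins["initial"]),
    lr.height_field(traj, leaflets, wins["final"]), region)
print(f"ring fit: centre=({region.center[0]:.1f}, {region.center[1]:.1f}) nm, "
      f"radius={region.radius:.1f} nm")
print(f"depression: mean {10*dep.depth:.1f} A, peak {10*dep.depth_min:.1f} A")
```

prints

```
RDF peak: 0.49 nm
species  residue_seq  frequency
   PHB1           41        1.0
   PHB1           55        1.0
   PHB2           39        1.0
ring fit: centre=(18.0, 18.0) nm, radius=10.0 nm
depression: mean 5.3 A, peak 8.0 A
```

The pair-correlation peak sits at the 0.5 nm tether distance (direct
headgroup–residue contact); residues holding tethered cardiolipin stay in
contact essentially permanently; the circle fit recovers the generator's
ring (centre of the 36 nm box, 10 nm radius); and the 0.7 nm (7 Å) Gaussian
invagination is read back as a 5.3 Å mean / 8.0 Å peak depression of the
central disk relative to the far field — the mean is smaller than the peak
because the Gaussian decays across the disk.

The same analyses run from the shell:

```sh
lipidring all --preset desk --seed 0 --out run0     # every stage, tidy CSV/JSON
lipidring simulate --preset desk --seed 0 --out sim --gro   # GRO/XTC export
lipidring report --run-dir run0                     # PNG heatmaps
```

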