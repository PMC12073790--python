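# Methods

`sambrush` reconstructs, at desk scale, the computational pipeline used to
characterise peptide self-assembled monolayers on gold nanostructure
surfaces and their interaction with the immune-checkpoint protein PD-L1:
monolayer construction, synthetic trajectory generation, and the analysis
stack (density profiles, contact scoring, SASA, surface morphology,
tensile deformability).

## Coordinate and unit conventions

All internal lengths are nm, times ps, masses u, densities kg/m³.  Unit
conversion happens only at file-format boundaries (PDB stores Å).  The
gold plane defines Z = 0 with Z increasing toward the solvent, so every
profile quantity reads directly as "distance from the gold surface".
Periodicity is XY-only (minimum image); Z is non-periodic, as appropriate
for a slab with a surface at the bottom.

## Monolayer construction

The model gold surface is a single in-plane hexagonally close-packed
(triangular) layer with nearest-neighbour spacing 0.288 nm (bulk-gold
value; configurable).  Conjugates are grafted with the chain axis along
+Z: the anchor sulfur sits exactly 0.294 nm above the gold plane, linker
and peptide units follow with fixed per-unit rises (0.35 nm per amino
acid — a 12-mer then spans ~4.2 nm, the elongated-state estimate — and
0.28 nm per ethylene-oxide monomer; O2oc counts as two monomers).  Anchor
sites form a uniform grid over the box with a seeded jitter of ±10 % of
the grid pitch and a minimum anchor separation of 0.5 nm; energy-based
packing is deliberately avoided since all downstream analyses run on
synthetic dynamics.  The PEG-3000 linker is represented as 68 monomers of
44 Da.

Formal charges use fixed neutral-pH rules: Arg/Lys +1, His 0, Asp/Glu −1,
thiol- or gold-bound Cys 0, amidated C-terminus and blocked N-terminus 0.
Chloride counterions (n_peptides × formal charge) are scattered in the
solvent region above the monolayer.  Water is implicit everywhere; the
reference systems' water counts are carried as metadata only.

The three preset systems are:

| preset     | conjugate                          | peptides | box (nm)            | Cl⁻ |
|------------|------------------------------------|----------|---------------------|-----|
| NS@P-CLP   | HS-PEG-Lys₃-Gly₂-CLP002-NH₂        | 45       | 10.32 × 9.99 × 27.55| 180 |
| NS@P-SCLP  | HS-PEG-Lys₃-Gly₂-SCLP002-NH₂       | 45       | 10.30 × 9.97 × 27.50| 180 |
| NS@C-CLP   | Ac-Cys-(O2oc)₂-CLP002-NH₂          | 90       | 10.31 × 9.98 × 18.17| 90  |

The peptide head conformation is pluggable (the default is extended); the
reference "most stable conformation" coordinates are not available, so no
attempt is made to reproduce them.

## Synthetic dynamics

The generator produces overdamped (Brownian / Euler–Maruyama) bead-chain
trajectories in self-consistent simulation units (energy = u·nm²/ps²):

    x(t+dt) = x(t) + μ F(x) dt + sqrt(2 μ T dt) ξ

One bead represents one residue (flagged as Cα).  Chains carry a flexible
linker block and a semi-rigid peptide block: a bending potential
k(1 − cos φ) along the peptide (default k = 10) encodes the peptide's
stable elongated conformation; the linker has no bending term.  Beads of
different chains interact through a soft excluded volume
A(1 − r/d)² for r < d (d = 2 × bead radius; default radius 0.35 nm, the
thickness of a residue, so the layer is jammed at the study grafting
density) and, between peptide beads only, a contact attraction
−ε exp(−((r − d)/w)²) with its minimum at bead–bead contact.  ε is the
single dial that switches the morphology: ε = 0 leaves an unassociated
brush ("grid"); ε = 1.5 (the clustered default) draws the peptide blocks
of neighbouring chains into persistent bundles.  Bead 0 of each chain is
pinned to its graft site; a reflecting wall at Z = 0 stands in for the
gold surface with no explicit gold–bead attraction.

The tensile mode applies a constant force mass × a (default a = 0.01
nm/ps²) to every Cα bead along −Z, mirroring a constant-acceleration
stretching test; the deformability metric is the shift of the
density-weighted mean Z of the peptide moiety between a pull-free and a
pulled run of the same seed.

The optional rigid probe is a cylinder 3 nm wide and 4 nm deep (the
IgV-like domain proxy) built from bead rings; the lowest ring carries the
12 active-spot residue labels (Phe19, Asp26, Ile54, Tyr56, Gln66, Arg113,
Met115, Ala121, Asp122, Tyr123, Lys124, Arg125) so persistence maps can be
exercised synthetically.  By default the probe is held at a fixed pose;
a mobile variant diffuses vertically as a rigid body.

Default study conditions are 9 chains at 1.2 nm graft spacing (grafting
density ≈ 0.69 nm⁻², comparable to 45 chains on a ~10 × 10 nm patch),
4 linker + 12 peptide beads per chain, bond length 0.35 nm, timestep
0.01 ps for 16 000 steps (160 ps) saving every 100 steps.  The default
initial conformation is the upright all-trans construction geometry (the
same convention the builder uses); a near-equilibrium seeded-coil start
(clearance-aware random walk for the linker, persistent tilted direction
for the peptide rod) is available as an option.  These sizes were chosen
so a full morphology comparison across five replica seeds completes in
minutes on one CPU; they are desk-scale stand-ins, not reproductions of
the reference 100 ns explicit-solvent runs.

What the generator emulates: grafted-chain connectivity, tunable
clustering, slab geometry, jamming at realistic grafting density, pulling,
and a protein-like rigid contact partner.  What it does not: solvent and
hydration forces, electrostatics, sequence-specific residue interactions,
secondary-structure changes, and physical kinetics.  Tests passing on
synthetic data therefore validate the *analysis* implementations and the
qualitative morphology contrasts, not any quantitative property of the
laboratory system.

## Analyses

**Density profiles** are mass-weighted histograms over Z in fixed slices
(default 0.15 nm), averaged over an analysis window, in kg/m³; atoms are
binned by point position.  Mass is conserved to better than 1e-6
(relative) by construction.  The monolayer extent metric is the outermost
distance at which the profile falls through 200 kg/m³, linearly
interpolated between slice centres; the outermost-crossing rule is used
because profiles need not be monotone near the surface.  The "average
density shift" of the tensile test is implemented as the density-weighted
mean Z (the unique moment-based reading of an otherwise loosely specified
quantity).

**Contact scoring** uses the rational switching function
s(r) = [1 − (r/r0)⁶] / [1 − (r/r0)¹⁴] with r0 = 0.6 nm, the analytic
limit 6/14 at r = r0, summed over heavy-atom pairs of different peptides
and optionally normalized by n(n−1)/2.  The pair sum is truncated at
5 × r0, where the term is below 1e-5; neighbour search uses a KD-tree
periodic in XY.  Close contacts use strict r < 0.5 nm between heavy atoms
of disjoint selections.  Persistence maps count, per peptide-residue
position × active spot, the frames with any heavy-atom pair below 0.5 nm,
times the frame interval (ns); cells are bounded by the window length.
The contact-potential energy is a plain sum of residue-pair matrix values
over contacting residue pairs; the matrix is a required input with no
default, since no published values ship with this package.  The 0.5 and
0.7 nm cutoffs are atomistic conventions; when a contact analysis runs on
the coarse bead model, whose residue-thick beads already touch at 0.7 nm,
the probe-contact driver scales the close-contact threshold to 0.9 nm and
says so in its output.

**SASA** is Shrake–Rupley with a deterministic Fibonacci point lattice
(default 960 points; two-sphere closed-form agreement within 2/√n and
<1 % drift against 3840 points).  Two probes are used throughout:
0.15 nm (water-like) and 1.5 nm (protein-like, approximating the IgV
domain scale).  Selection atoms are the only occluders, and periodic
images are ignored — appropriate for patches comfortably smaller than the
box.  The patch-to-nanoparticle scale-up is the exact area ratio
Δ × 4πR²/A_patch.

**Surface morphology** renders the monolayer's top surface (max of
z + vdW radius per XY grid cell, nearest-neighbour filled) at 0.2 nm
resolution.  Pockets are connected components more than 1.5 nm below the
90th-percentile surface level; depth is measured to the deepest cell,
width as the largest inscribed disc (2 × (max EDT + 0.5) × resolution).
Both carry ~one-cell discretization error, so the probe-accommodation
check (depth ≥ 4 nm, width ≥ 3 nm) allows one grid resolution of slack.
For trajectories, the per-cell top surface may be averaged over a window
("mean height map") so that transient thermal gaps wash out and only
persistent morphological pockets remain.

### What the morphology dial can and cannot reproduce

The clustered member reliably shows the expected excess of inter-peptide
contacts: the normalized S function is an order of magnitude above the
ε = 0 brush in every replica (`analysis/02_morphology_pair.py` computes
this table).  The accessibility and deformability contrasts, however, run
the other way in this surrogate: because attraction is the only
difference between the pair and there is no solvent, switching it on
monotonically compacts the grafted layer downward and smooths it
laterally, so the clustered member ends up *lower*, with *shallower*
persistent pockets, *smaller* per-peptide large-probe SASA and a
*smaller* tensile centroid shift than the brush.  This held across every
regime explored (thin or residue-thick beads, flexible or semi-rigid
peptides, sparse to jammed grafting, coil or extended starts, ε from 0.5
to 6, Gaussian or contact-well attractions).  In the laboratory system
those contrasts are solvent-mediated — hydration keeps the clustered
peptides extended and elevated on their long PEG linkers — which an
implicit-solvent Brownian surrogate with a neutral reflecting wall cannot
express.  The corresponding acceptance tests assert the orderings the
reference observations imply and are expected to fail on this surrogate;
they are retained unmodified as an honest record of this limitation.

## Numerical choices and degenerate inputs

The integrator raises a stability error when a deterministic displacement
exceeds one bond length in a single step.  The angle-bending gradient
floors bond lengths at 0.15 nm (the exact 1/(|b₁||b₂|) gradient diverges
when crowding transiently compresses a bond).  Switch-function evaluation at
|r/r0 − 1| < 1e-9 returns the analytic limit.  Threshold crossing on a
profile that never reaches the threshold returns a sentinel (None).
Persistence analysis on topologies missing an active spot fails with the
list of absentees.  Empty selections and empty analysis windows raise
analysis errors rather than returning empty aggregates, except the
convergence series, which warns and returns an empty series when no
peptide qualifies (mirroring how such a run would be interpreted: no
contact formed).

## Known limitations

- The Brownian surrogate has no solvent; hydration-driven effects (e.g.
  SASA contrasts caused by water structuring) are represented only through
  the geometric consequences of clustering.
- Bead radii are uniform per run; atomic-resolution united-atom radii are
  used only for file-derived topologies.
- Pocket width via inscribed discs underestimates elongated pockets'
  usable width.
- The morphology pair differs only in the inter-chain attraction; real
  sequence scrambling also changes peptide–solvent interactions, which
  the surrogate cannot separate.
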