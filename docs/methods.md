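# Methods

This note records the models, conventions and numerical choices behind the
package, and what its verification strategy does and does not demonstrate.

## Observables and conventions

**Order parameter.** For every explicit C–H bond of a requested carbon
site, *S*<sub>CH</sub> = ⟨(3 cos²θ − 1)/2⟩ with θ the angle between the
C–H vector and the bilayer normal (the z axis).  Averaging order: hydrogens
of a carbon → lipids of the species (one value per frame) → frames.  The
frame-to-frame scatter gives the standard error; frames are treated as
independent (no autocorrelation correction), which is exact for the
synthetic generator and an approximation for real trajectories.  Both the
signed value and |*S*<sub>CH</sub>| are reported.  Only all-atom systems
are supported; there is no united-atom hydrogen reconstruction.

**Tilt angles.** The headgroup vector runs P→N for phosphatidylcholine and
P→Cα (the serine carbon bonded to the ammonium group, CHARMM name C12) for
phosphatidylserine; the alternative P–N definition for PS can be selected
through a topology override.  Chain vectors are the director from the
terminal carbon toward the glycerol-end carbon.  The reference normal is +z
for the upper leaflet and −z for the lower, which pools the two leaflets
into one unimodal [0°, 180°] distribution; without the sign flip, pooled
head-tilt histograms of a symmetric bilayer would be bimodal.  Histograms
use 1° bins by default; the mean is computed from the raw angles, the mode
is the centre of the maximum bin (ties resolve to the lower angle).

**Area per lipid.** Per frame and leaflet, the lipids' phosphorus atoms are
projected onto the xy plane and tessellated with a periodic 2-D Voronoi
diagram, implemented by replicating the seeds into the 8 neighbouring
lateral images and keeping the central copies' cells — exact for
orthorhombic boxes.  Cell areas are required to sum to the box
cross-section within 10⁻⁶ relative (a violated sum raises, since it can
only indicate a defect).  Coincident seeds are perturbed by a
deterministic ~10⁻⁶ nm jitter and logged.  Per-species APL is the mean cell
area over lipids, leaflets and frames.

**Thickness.** *d*<sub>P</sub> is the difference of the leaflet-mean
phosphorus z positions, per frame, averaged over frames.  Leaflets are
assigned per frame by phosphorus z relative to the mean phosphorus z of the
whole bilayer; flip-flop is not tracked.

**Density profiles.** Each frame is re-centred at the mean phosphorus z
(the only headgroup atom every analysis uses) before binning, with default
0.1 nm bins spanning the box; mass comes from standard atomic weights with
the element inferred from the atom name, plus a united water site ("MW",
18.015 u).  Units: 1 u/nm³ = 1.66054 kg/m³.  Profiles are not symmetrised
across leaflets.

**Contacts, RDFs, clusters.** Two molecules are in contact when any
inter-atomic minimum-image distance is within the cutoff (default 0.6 nm).
Counting uses a periodic k-d tree (cell-list equivalent); an O(N²)
27-image brute-force oracle is kept in the test suite and matches exactly
on small frames.  The k-d tree ball query closes the boundary (≤ cutoff);
boundary-equal distances have measure zero for continuous data.  Lateral
RDFs are two-dimensional and per-leaflet, computed on phosphorus positions,
normalised by the ideal-gas annulus count at the leaflet's mean density,
capped at half the shorter lateral box length.  Like-lipid clusters are
connected components of the same-species contact graph within one leaflet.

**Monolayer thermodynamics.** Isotherms are cleaned to strictly decreasing
area (collapse/plateau points dropped and logged) before any derivative or
interpolation.  For *C*<sub>s</sub>⁻¹ = −A (∂π/∂A), π is resampled onto a
uniform area grid and differentiated with a quadratic Savitzky–Golay filter
(default 11-point window): film-balance data are noisy and the smoothing
window, not raw differencing, sets the noise floor; the window is
configurable.  The Davies–Rideal bands use closed lower / open upper
bounds (gaseous < 12.5 ≤ liquid-expanded < 50 ≤ liquid < 100 ≤
liquid-condensed < 250 ≤ solid, mN/m).  ΔG<sup>exc</sup> integrates the
interpolated excess area by the trapezoidal rule from the lowest commonly
recorded pressure to π* (default 30 mN/m, where monolayer properties track
bilayers); the unmeasured segment below that start is taken as zero excess
provided it spans at most 1 mN/m, otherwise the record is rejected.  The
conversion 1 mN/m · nm² · *N*<sub>A</sub> = 0.6022 kJ/mol is applied
explicitly.  The literature threshold of 0.8–1.2 kJ/mol for incipient
phase separation is attached to reports as an annotation only.

## The synthetic generator

The generator emulates the statistical structure of a mixed-bilayer
ensemble, not its dynamics or energetics:

* lipids sit on a per-leaflet square lattice whose spacing encodes the
  mole-fraction-weighted mean APL, with Gaussian lateral jitter (default
  0.05 nm) and vertical noise on the P planes at ±*d*<sub>P</sub>/2
  (default σ 0.1 nm);
* head vectors are drawn on a fixed cone (exact expectations) or a
  reflected-Gaussian polar law (for mode recovery), azimuth uniform;
* chains are straight rods at a fixed tilt; C–H unit vectors sit on the
  cone θ = arccos(√((2S + 1)/3)) that reproduces the target order
  parameter exactly, independent of azimuth sampling;
* water is carried by single-site pseudo-atoms filling the two slabs
  outside the membrane; K⁺ counterions (one per anionic lipid) follow
  Gaussian z-laws just outside the P planes;
* frames are independent redraws, so recovery tolerances legitimately
  scale as 1/√(n frames); identical spec + seed gives bit-identical
  output.

Defaults mirror the target study conditions: 100 lipids per leaflet, 100
frames, 50 waters per lipid.  Species are assigned to lattice sites by a
seeded shuffle ("mixed") or contiguously ("clustered", to exercise the
cluster statistics in both regimes).

Because all species share one lattice, Voronoi conservation pins every
species' expected cell area at the lattice mean: in mixtures the ground
truth records that effective value, while pure bilayers recover their
configured APL exactly.  Passing recovery tests therefore demonstrates the
estimators are unbiased under known noise — not that the generator captures
chain dihedral disorder, headgroup conformational coupling, temporal
correlation, or electrostatics of real membranes.

The isotherm generator uses exponential compression laws
A(π) = A₀ e^(−π/K), for which *C*<sub>s</sub>⁻¹ = K identically, plus a
constant excess-area term for mixtures, for which
ΔG<sup>exc</sup>(π*) = 0.6022 · a · π* in closed form.  Families are
sampled from π = 0 so the zero-pressure limit of the integral is exact.

## Numerical choices and degenerate inputs

* Only orthorhombic boxes: every analysis separates along z; triclinic
  input raises at parse time.
* Coordinates are stored in nm; PDB Å are converted at read.  GRO
  round-trips are exact to the format's 10⁻³ nm printing precision.
* Atom selection is exact residue-name + atom-name matching; species
  conventions default to CHARMM36 naming (sn-1 palmitoyl C31–C316, sn-2
  oleoyl C21–C218) and are overridable via YAML, so other force fields'
  naming can be mapped without code changes.
* Degenerate bilayers (all phosphorus at one z) raise; a leaflet with
  fewer than 3 lipids cannot be tessellated and raises.
* Savitzky–Golay end stencils are biased by curvature; closed-form
  comparisons exclude the outermost half-window on each end.
* Statistical recovery tests fix ≥20 seeds and a 3-standard-error
  tolerance, which makes the checks deterministic under the pinned seeds.

## Problem sizes

Recovery protocols default to 100 lipids per leaflet × 100 frames × 20
seeds for thickness and APL, 10 000 lipids × 20 seeds for tilt laws, and
200-point isotherm constructions — sizes at which every stochastic
estimate's standard error is far below the scientific tolerances being
checked, while a full verification run completes in about a minute on one
CPU.

## Known limitations

* No interaction energies, no lipid flip-flop, no ion-binding kinetics,
  no 3-D Voronoi volumes, no triclinic boxes, no topology inference from
  connectivity.
* Frame independence is assumed in all error bars; correlated MD frames
  will make the reported standard errors optimistic unless the input is
  subsampled.
* The generator's chains are rigid rods: chain *S*<sub>CH</sub> profiles
  with realistic plateau-decay shapes must be encoded site-by-site via the
  per-site targets rather than emerging from conformational sampling.
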