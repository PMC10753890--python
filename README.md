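# lamella

Structural analysis of mixed lipid bilayers and thermodynamic analysis of
Langmuir monolayers, built for studies of zwitterionic/anionic mixtures such
as POPC/POPS — systems where the two lipids share identical acyl chains and
the headgroup chemistry alone drives packing, ordering and (non-)ideal
mixing.

The package answers two kinds of question:

* **From molecular configurations** (GRO/PDB, multi-frame): how are the
  lipids arranged?  It computes C–H bond order parameters
  *S*<sub>CH</sub> = ⟨(3 cos²θ − 1)/2⟩, headgroup and acyl-chain tilt-angle
  distributions relative to the bilayer normal, per-species area per lipid
  (APL) from a periodic 2-D Voronoi tessellation of the phosphorus
  positions, bilayer thickness *d*<sub>P</sub> (phosphorus plane
  separation), mass density profiles along *z*, intermolecular contact
  counts at a 0.6 nm cutoff, lateral per-leaflet radial distribution
  functions, and like-lipid cluster statistics.
* **From π–A isotherms** (surface pressure mN/m vs area per molecule nm²):
  how do the film components mix?  It computes the compression modulus
  *C*<sub>s</sub>⁻¹ = −A (∂π/∂A), classifies the film on the Davies–Rideal
  scale (50–100 mN/m → liquid), and quantifies mixing through the excess
  area *A*<sup>exc</sup> = *A*₁₂ − (*X*₁*A*₁ + *X*₂*A*₂) and the excess free
  energy of mixing ΔG<sup>exc</sup> = *N*<sub>A</sub> ∫₀^π* *A*<sup>exc</sup> dπ
  (1 mN/m · nm² · *N*<sub>A</sub> = 0.6022 kJ/mol).

Because raw trajectories for such studies are rarely deposited, the package
ships a **synthetic-data module**: it generates bilayer trajectories and
isotherm families whose ground truth (APL, *d*<sub>P</sub>, tilt laws,
per-site *S*<sub>CH</sub>, closed-form *C*<sub>s</sub>⁻¹ and
ΔG<sup>exc</sup>) is known exactly, so every analysis stage is verified by
parameter recovery.

## Worked example

Generate a mixed bilayer at X<sub>POPS</sub> = 0.2 (80 POPC + 20 POPS per
leaflet, 50 independent frames) and recover its configured structure:

```python
from lamella import (BilayerSpec, TiltLaw, generate_bilayer, voronoi_apl,
                     bilayer_thickness, tilt_distribution, order_parameters,
                     default_topologies)

topos = default_topologies()
spec = BilayerSpec(
    n_per_leaflet={"POPC": 80, "POPS": 20},
    apl={"POPC": 0.622, "POPS": 0.597},      # nm^2
    d_p=4.00,                                # nm
    head_tilt={"POPC": TiltLaw(66.0), "POPS": TiltLaw(63.0)},
    chain_tilt={"POPC": 25.0, "POPS": 20.0},
    s_ch={"POPC": {"C32": -0.21}},
    n_frames=50, waters_per_lipid=5.0, seed=11)
frames, truth = generate_bilayer(spec)

apl = voronoi_apl(frames, topos)
d_p = bilayer_thickness(frames, topos)
tilt = tilt_distribution(frames, topos["POPC"], "head", leaflet_topologies=topos)
s_ch = order_parameters(frames, topos["POPC"], sites=["C32"])

print(f"APL (nm^2):  {apl.per_species}")
print(f"d_P (nm):    {d_p.mean:.3f} +/- {d_p.sd:.3f}")
print(f"theta_PC:    mean {tilt.mean:.2f} deg, mode {tilt.mode:.1f} deg")
print(f"|S_CH|(C32): {s_ch.s_ch_abs[0]:.3f}")
```

Output:

```
APL (nm^2):  {'POPC': 0.6171430136350728, 'POPS': 0.6164279454597087}
d_P (nm):    3.999 +/- 0.013
theta_PC:    mean 66.00 deg, mode 66.5 deg
|S_CH|(C32): 0.210
```

The thickness, tilt and order parameter come back at their configured
values.  The two species share one lattice, so Voronoi area conservation
pins both recovered APLs at the lattice mean (0.617 nm² here); pure-species
bilayers recover their configured APL exactly (see `docs/methods.md`).

A command-line interface wraps the same library:

```sh
lamella generate-synthetic --spec spec.yaml --out-dir data/
lamella analyze-bilayer --trajectory data/trajectory.gro --out-dir report/
lamella analyze-isotherms --manifest isotherms.yaml --out-dir mono/
lamella selftest
```

`analyze-bilayer` writes one TSV per observable plus a per-species
APL / *d*<sub>P</sub> summary table; `analyze-isotherms` writes the
*C*<sub>s</sub>⁻¹ curves with maxima and Davies–Rideal state labels and the
*A*₁₂ / ideal / *A*<sup>exc</sup> / ΔG<sup>exc</sup> table at the analysis
pressure (default 30 mN/m).

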