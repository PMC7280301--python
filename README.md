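# vesselvfm

Regional inverse material characterization of thick-walled, dissected
vessel segments by the virtual fields method (VFM).

Dissecting aneurysms — such as those of the suprarenal abdominal aorta in
AngII-infused *ApoE⁻/⁻* mice — produce walls that are thick, heterogeneous
and partially filled with intramural thrombus, which rules out classical
thin-wall biaxial characterization. `vesselvfm` is for vascular
biomechanics researchers who have (or want to simulate) full-field
deformation measurements of such segments under inflation–extension:
surface displacements on the adventitia (panoramic DIC-style grids) and
in-plane displacements across the wall (OCT-based digital volume
correlation lattices). The package fuses the two into a continuous
transmural deformation-gradient field and identifies sector-wise material
parameters, from which it maps circumferential stretch, circumferential
Cauchy stress, linearized circumferential stiffness and stored energy over
the lesion. A histology module relates those maps to constituent area
fractions (fibrin, collagen, elastin) of stained cross-sections.

## Model and method

The wall is a constrained-mixture, four-fiber-family hyperelastic solid;
the thrombus is neoHookean. Per unit reference volume,

```
W = 𝕀_wall [ Σ_{i=1..3} W^i(F̄) + (c⁴/2)(‖F̄G₄‖² − 3) ] + 𝕀_imt (c⁵/2)(tr F̄ᵀF̄ − 3)

W^i = c^i/(4k^i) [ (e^{k^i ⟨I_i−1⟩₊²} − 1) + α (e^{k^i ⟨I_i−1⟩₋²} − 1) ],
I_i = |F̄ G_i a_i|²
```

with fiber directions a₁ = e_c (circumferential), a₂ = e_a (axial),
a₃± = cos β e_c ± sin β e_a (both diagonals share c³, k³), deposition
stretch tensors G_i encoding the prestretch at which constituents were
incorporated, and F̄ the isochoric deformation gradient relative to the
pressurized in vivo reference state (80 mmHg at the in vivo axial stretch).

Identification uses the principle of virtual power with trace-free virtual
fields (a pressure-normalized radial 1/r family and a force-normalized
axial family, Gaussian-localized on each material sector), so the
incompressible reaction pressure drops out exactly. Because W is linear in
the moduli c¹..c⁵, each (virtual field, load state) pair gives one linear
equation, A(Ξ){c} = {P*_ext}; the moduli are solved by least squares inside
a seeded global search (differential evolution by default, a classical
real-coded genetic algorithm optionally) over the nonlinear set Ξ = (k¹..k³,
G¹..G⁴, β, α) per sector. See `docs/methods.md` for every numerical choice.

No measured datasets are shipped; a forward generator produces the full
input bundle (mesh, grids, load schedule) from an incompressible
thick-walled tube solution with known ground truth, under the measurement
protocol (7 pressures × 3 axial stretches, in-plane-only volumetric data,
10–15 µm class noise).

## Worked example

Simulate a homogeneous specimen, build the model, and fit with the
nonlinear set frozen at its true values (a pure linear solve, seconds;
drop `fixed` to run the full global search, minutes):

```python
import numpy as np
from vesselvfm.synthetic import TubeScenario, sample_measurements
from vesselvfm.model import VesselVFMModel
from vesselvfm.vfm import IdentificationConfig

sc = TubeScenario(noise_surface_um=0.0, noise_volume_um=0.0,
                  mesh_ntheta=24, mesh_nz=8, mesh_nr=2,
                  surface_grid=(36, 16), volume_shape=(32, 32, 40), seed=7)
b = sample_measurements(sc)            # forward truth + emulated grids
t = sc.wall                            # ground-truth parameters
cfg = IdentificationConfig(
    n_theta=1, n_z=1, G_a=sc.G_a,
    fixed={"k1": t.k1, "k2": t.k2, "k3": t.k3, "G1": t.G1, "G2": t.G2,
           "G3": t.G3, "G4": t.G4, "beta": t.beta, "alpha": t.alpha})
model = VesselVFMModel(b.mesh, b.surface, b.volume, b.schedule, cfg)
res = model.fit(seed=0)
print(res.summary())
```

prints

```
Virtual Fields Identification Results
======================================================
sectors:              1 x 1
load states:          21
linear unknowns:      4
cost H:               0.000867988
relative residual:    4.546e-03
system rank:          4

 i_theta  i_z    c1    c2    c3    c4  c5  k1  k2  k3   G1   G2   G3    G4  beta_deg  alpha
       0    0 14.29 9.869 20.09 30.53   0 0.8 0.5 1.2 1.08 1.08 1.08 1.223        40    0.1
```

The recovered moduli sit within a few percent of the truth (c¹..c⁴ = 15,
10, 20, 30 kPa): the 0.5 % relative residual reflects the linear-in-R
transverse blend of the displacement reconstruction, not the solver. Derived maps follow
from the results object:

```python
maps = res.metric_maps()   # stretch/stress/stiffness @140 mmHg, energy @80
print(np.median(maps["circ_stretch"]))        # 1.183
print(np.median(maps["circ_stress_kpa"]))     # 87.5  (kPa)
print(np.median(maps["circ_stiffness_mpa"]))  # 0.33  (MPa)
print(np.median(maps["stored_energy_kpa"]))   # 7.88  (kPa)
```

i.e. at 140 mmHg this synthetic vessel is stretched ~18 % beyond its
80 mmHg reference, carries a median circumferential stress of ~88 kPa and
a linearized circumferential stiffness of ~0.3 MPa, and stores ~8 kPa of
elastic energy at the reference pressure.

A command-line interface mirrors the pipeline:

```
vesselvfm simulate --out data/            # write mesh + grids + schedule
vesselvfm fuse --mesh data/mesh.vtk --surface data/surface.tsv \
               --volume data/volume.tsv --schedule data/schedule.csv \
               --out fuse_report.csv
vesselvfm identify --mesh data/mesh.vtk --surface data/surface.tsv \
                   --volume data/volume.tsv --schedule data/schedule.csv \
                   --n-theta 2 --n-z 2 --seed 1 --out params.csv
vesselvfm histology --demo --out fractions.csv
vesselvfm correlate --table fractions.csv --x fibrin --y collagen
```

Meshes are legacy ASCII VTK unstructured grids (tet cells with an integer
cell-data array `region`, 0 = wall / 1 = thrombus; boundary triangulations
as `<stem>_inner.vtk` / `<stem>_outer.vtk`); displacement grids are TSV
tables with one column per state and component; schedules and parameter
tables are CSV with a one-line metadata header.

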