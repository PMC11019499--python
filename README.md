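# lamella

Analysis toolkit for ethanol-induced structural changes in lamellar-phase
liposomes, combining three views of the same system:

1. **SAXS Bragg analysis** — detect Bragg orders in 1-D scattering profiles
   of multilamellar vesicles, fit the lamellar repeat distance *d*, classify
   uni- vs multilamellar profiles, and track *d* across contact times in a
   microfluidic dilution experiment.
2. **Coarse-grained trajectory metrics** — structure factor along the
   stacking normal, number-density profiles, area per lipid, the
   phosphate–phosphate thickness *d*<sub>PP</sub>, segmental order
   parameters, chain-angle distributions, leaflet assignment, lipid
   flip-flop detection, and ethanol penetration into the membrane core.
3. **Microfluidic mixing bookkeeping** — fully-mixed ethanol fraction set by
   the flow-rate ratio, the position↔residence-time map, and a 2-D
   plug-flow advection–diffusion model of cross-channel ethanol transport.

A synthetic-data generator fabricates stacked CG POPC bilayers and lamellar
SAXS profiles with *planted* structural parameters, so every analysis stage
is tested against known ground truth without beamline data or MD runs.

## The model in brief

A stack of bilayers with repeat distance *d* scatters at
*q<sub>n</sub>* = 2π*n*/*d*.  Detected peaks are assigned integer orders by
their ratio to the lowest peak, and *d* is fitted through the origin:

    slope = Σ n·q_n / Σ n²,    d = 2π / slope

From simulation coordinates the lamellar-normal structure factor is

    F(q) = Σ_k f_k exp(i q z_k),    I(q) = |F(q)|² P

with *f<sub>k</sub>* = 1 by default, on the periodicity-compatible grid
*q* = 2π*m*/*L<sub>z</sub>*.  Tail order is quantified per bond as
*S* = ⟨(3 cos²ϑ − 1)/2⟩, where ϑ is the bond angle to the bilayer normal
(1 aligned, 0 isotropic, −0.5 in-plane).  In the flow-focusing channel the
fully mixed ethanol fraction is *c*<sub>stock</sub>·FRR/(FRR+1) and contact
time is *t* = *x*/*u* with *u* = *Q*/(width·depth).

## Worked example

```python
import numpy as np
from lamella import *
from lamella.synthetic import SAXSProfileSpec, generate_saxs_profile
from lamella.traj_metrics import bilayer_metrics, segmental_order

# --- a multilamellar profile with orders at 1.03 / 2.05 / 3.12 nm^-1
prof = generate_saxs_profile(SAXSProfileSpec(peak_centers=(1.03, 2.05, 3.12), seed=1))
call, fitted = analyze_profile(prof)
print("class:", call.label)                       # class: multilamellar
print(f"d = {fitted.d:.1f} nm")                   # d = 6.1 nm
print(f"hydration layer = {hydration_layer(fitted.d, 4.21).thickness:.1f} nm")
                                                  # hydration layer = 1.9 nm

# --- a three-bilayer CG stack with planted geometry
spec = LamellarSpec(n_bilayers=3, lipids_per_leaflet=100, seed=1)
frame = generate_lamellar_config(spec)
m = bilayer_metrics([frame], n_bilayers=3)
print(f"area per lipid = {m.area:.3f} nm^2")      # area per lipid = 0.647 nm^2
print("d_PP =", np.round(m.d_pp, 2), "nm")        # d_PP = [3.85 3.85 3.86] nm

# --- dilution bookkeeping
cs = ChannelSpec()
print(f"mixed fraction = {mixed_fraction(cs):.1f} vol%")   # 83.3 vol%
print(f"t(20 mm) = {residence_time(cs, 20.0):.1f} s")      # 16.8 s
field = solve_advection_diffusion(cs, x_max_mm=40.0)
print(f"ethanol at 1.7 s = {concentration_at_time(field, 1.7):.1f} vol%")  # 19.3 vol%
```

The first block says the profile carries three harmonically related Bragg
orders, i.e. an ordered multilamellar stack with a 6.1 nm repeat; after
subtracting a 4.21 nm bilayer-pair thickness, a ~1.9 nm water layer
separates the membranes.  The second block recovers the planted area per
lipid and membrane thickness from coordinates alone.  The third gives the
dilution endpoint (83%) and maps a 20 mm measurement position to 16.8 s of
ethanol contact.

A CLI mirrors these steps (`lamella synth-frame`, `lamella synth-saxs`,
`lamella analyze-profile`, `lamella analyze-series`, `lamella
mixing-profile`, `lamella mixing-at-time`).

## Documentation

`docs/methods.md` describes the models, the synthetic-data generator and
its planted parameters, numerical choices, and known limitations.
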