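# evcapture

Monte Carlo simulation and design calculators for **immunoaffinity capture of
extracellular vesicles (EVs) in micropillar-array microfluidic devices**.

Liquid-biopsy assays enrich disease-specific EVs (~50–250 nm membranous
nanoparticles) by flowing plasma through a microfluidic bed whose surfaces are
coated with monoclonal antibodies (mAbs) against a surface antigen such as
CD8α. The figure of merit is the *recovery* — the fraction of particles
entering the device that bind before exiting — and the engineering trade-off
is recovery vs throughput: slower flow gives particles more time to diffuse to
an antibody, but takes longer to process a sample. `evcapture` is for device
designers and assay developers who want to predict that trade-off before
cutting a mold.

## The model

The inter-pillar region is reduced to a 2D unit cell: a parallel-plate channel
of gap *h* equal to the inter-pillar spacing and length *L* equal to the bed
length. Each simulated particle is advanced by

* plane-Poiseuille convection, *u(y) = 6 ū (y/h)(1 − y/h)*, with mean
  interstitial velocity *ū = Q / A_open*,
* lateral and longitudinal Brownian displacements with variance *2 D Δt* per
  axis, where *D = k_B T / (3π η d)* is the Stokes–Einstein diffusivity of a
  particle of diameter *d*, and
* antibody binding at the walls with a Chang–Hammer forward rate: the
  intrinsic on-rate attenuated by the encounter Péclet number
  *Pe = a v / D* (encounter radius *a* ≈ 10 nm, near-wall slip velocity *v*),
  *k_f = k_in n_antigen / (1 + Pe/2)*.

Wall binding is realised as a partially absorbing (Robin) boundary with uptake
velocity *k_w = k_f ρ_mAb a*, using the Erban–Chapman crossing scheme, so the
bound fraction is insensitive to the time step. Particles are tracked until
bound or lost at *x = L*; batches repeat until the binomial confidence
interval of the recovery is tighter than a set tolerance. Serial beds compose
as survival products, 1 − Π(1 − rᵢ); parallel beds split the flow evenly.

Deterministic design calculators cover the rest of the planning arithmetic:
internal surface area of a pillar bed, monolayer EV load capacity
(hexagonal packing, π/(2√3) ≈ 0.9069), antibody coverage in pmole/cm²,
processing time, and throughput ratios between devices.

Two published device designs ship as fixtures: a 3-bed chip (122 mm flow
path, 100 µm circular pillars, 15 µm gaps) and a 7-bed parallel chip
(23 mm beds, 10 µm diamond pillars, 10 µm gaps).

## Worked example

```sh
$ evcapture geometry report src/evcapture/data/evmap_7bed.yaml
{
 "name": "evmap_7bed",
 "arrangement": "parallel",
 "n_beds": 7,
 "internal_surface_area_cm2": 38.154816,
 "internal_volume_ul": 21.60144,
 "open_cross_section_m2": 6.3e-07,
 "ev_load_capacity": 195810607008.71677
}
```

38.2 cm² of capture surface across the 7 beds, which as a hexagonal monolayer
of 150 nm vesicles could hold ~2×10¹¹ particles — orders of magnitude above a
typical 100 µL plasma load (~10⁸–10⁹ particles), so capture stays in the
linear regime (`capacity_guard` checks this per run).

```sh
$ evcapture simulate --device src/evcapture/data/evmap_7bed.yaml \
    --kinetics src/evcapture/data/kinetics_cd8_ev.yaml \
    --flow 5,10,20 --particles 5000 --seed 42 --out sweep.csv
$ cat sweep.csv
flow_ul_min,recovery,ci_low,ci_high,n_bound,n_lost,batches,converged
5,0.99470000000000003,0.9930745948998293,0.99594547711222325,9947,53,2,True
10,0.92126666666666668,0.91684803918669888,0.92546957891704174,13819,1181,3,True
20,0.72145714285714291,0.71673663116872877,0.72612904739506268,25251,9749,7,True
```

Predicted recovery falls from 99.5% at 5 µL/min to 72% at 20 µL/min as the
residence time shrinks — the recovery/throughput trade-off quantified. A JSON
run record (config, seed, software version, per-batch trace) is written next
to every CSV so any sweep can be re-executed bit-identically.

```sh
$ evcapture plan --device src/evcapture/data/evmap_3bed.yaml --volume 100 --flow 0.5
200.0 min (3.33 h)
$ evcapture compare src/evcapture/data/evmap_7bed.yaml src/evcapture/data/evmap_3bed.yaml
throughput ratio: 8.24
```

At matched channel velocity the 7-bed device processes sample ~8× faster than
the 3-bed device (ratio of total flow cross-sections).

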