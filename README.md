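# angiosim

Dynamic three-dimensional simulation of sprouting angiogenesis,
structural adaptation and pruning in cerebral cortex.

## What it is

During early development of the rodent brain, a vascular plexus on the
cortical surface (the pial vasculature) sends sprouts into the tissue,
which connect into a perfused three-dimensional microvascular network;
at the same time the direct arteriolar-venular (A-V) shunt on the
surface regresses, so that flow is forced through the cortical depth.
`angiosim` models this process mechanistically in a hexagonally
periodic prism of cortical tissue (side 150 um, height 500 um),
starting from a single flowing pial vessel plus one penetrating
arteriolar and one venular sprout, and runs the coupled loop:

1. **Hemodynamics** — Poiseuille network flow `R = 128 L eta_app /
   (pi D^4)` with the empirical diameter- and hematocrit-dependent
   apparent viscosity of blood (Fahraeus-Lindqvist effect, in-vivo
   law), red-cell phase separation at diverging bifurcations, and wall
   shear stress `tau_w = D dP / (4 L)`.
2. **Oxygen transport** — quasi-steady Green's-function solution of
   `K lap(P_O2) = M(P_O2)` with Michaelis-Menten consumption
   `M = M0 P/(P_c + P)`, coupled to convected intravascular oxygen
   `f(P_b) = Q [H_D C0 S(P_b) + alpha_eff P_b]` with Hill saturation
   `S = P^n/(P^n + P50^n)` and lumped intravascular resistance.
   Vessel subsegments act as discrete sources, tissue points as
   Michaelis-Menten sinks; their free-space kernel fields superpose
   with in-plane periodic images, no-flux mirrors at the slab faces
   and a far-field closure that conserves oxygen exactly.
3. **Growth factor (GF)** — released in hypoxic tissue at rate
   `M_GF = K_GF C_GF0 / (1 + (P_O2/P_GF)^N_GF)`, diffusing with linear
   degradation (screened kernel, decay length
   `L_GF = sqrt(D_GF/K_GF) = 50 um`).
4. **Angiogenesis** — stochastic sprouting at probability
   `P = k_p l dt (C_GF - C_th)/(C_th50 + C_GF - C_th)` above the GF
   threshold; tips advance at `V_g`, steered by random rotation
   (variance `sigma_s`), filopodial homing to vessels within a 25-um
   forward cone, and the GF gradient; a tip within 5 um of another
   segment connects, and new A-V pathways start to flow.
5. **Remodeling** — tension-driven node migration above a curvature
   threshold; diameter adaptation
   `dD = D [ln(tau_w + tau_ref) - ln tau_e(P) + k_m (S_m + S_c)/D - k_s] dt/T`
   with a downstream-convected metabolic signal S_m and an
   upstream-conducted signal S_c (decay length 1.73 cm); vessels below
   the 3-um red-cell minimum are pruned together with everything their
   loss disconnects.

The modeled developmental endpoint is a stable, fully-oxygenated
network within the 10-day window with the pial A-V shunt pruned, so
that flow reroutes through the penetrating vessels as observed in the
developing mouse cortex. Whether a simulation reaches that endpoint
turns out to hinge on the early competition between the surface shunt
and the penetrating tree, which is sensitive to modeling choices the
sources leave open; see `docs/methods.md` (Known limitations) for what
the current defaults produce and why.

## Who it is for

Researchers in microvascular physiology and systems biology who need
mechanistically generated, hemodynamically consistent 3D microvascular
networks (e.g. as substrates for oxygen-transport or neurovascular
modeling), or who want to probe which vascular response mechanisms
(metabolic sensitivity, conducted responses) are required for stable,
adequately perfusing network architectures.

## Worked example

```python
import angiosim as a

params = a.Parameters()             # reference parameter set
net = a.make_initial_network(params)
sol = a.iterate_flow(net, params)   # joint flow/hematocrit fixed point

q = next(s.flow for s in net.conducting_segments()
         if s.status == "fixed_resistance")
print(f"initial pial flow: {q:.1f} nl/min")

grid = a.generate_tissue_grid(a.build_hex_domain(150, 500), 20.0)
print(f"tissue points: {grid.n_points}")

blood, tissue = a.solve_oxygen_field(
    net, grid.points, grid.point_volume, params,
    domain=a.build_hex_domain(150, 500))
import numpy as np
print(f"initial hypoxic fraction: "
      f"{100 * np.mean(tissue.po2 < 20):.1f} %")
```

prints

```
initial pial flow: 40.2 nl/min
tissue points: 3675
initial hypoxic fraction: 98.4 %
```

40.2 nl/min is the flow driven by the 100/20 mmHg boundary pressures
through the pial vessel with its narrow fixed-resistance inlet; 3675
points is the 20-um tissue lattice of the reference hexagon; and a
single surface vessel leaves essentially the whole 500-um slab hypoxic
— the starting condition that drives sprouting.

A full simulation:

```python
result = a.run(params, seed=1)          # ~200 steps of 0.05 day
print(result.final_metrics["oxygen_extraction"])
print(result.pial_av_connected)         # False once the shunt prunes
```

Full runs at reference scale take on the order of hours on one CPU
(the Green's-function fields dominate); a scaled-down domain
(`Parameters(hex_side=100)`) runs about five times faster and shows
the same qualitative behavior.

There is also a CLI: `angiosim run --seed 1 --out out/`,
`angiosim fixtures initial`, `angiosim sweep k_m --low 12 --high 24`.
Run outputs are plain CSV/JSON plus legacy-VTK polydata snapshots for
3D viewing.

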