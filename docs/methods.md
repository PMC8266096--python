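# Methods

## Model overview

`angiosim` simulates the emergence of a three-dimensional cortical
microvascular network from a single pial flow pathway by iterating, at
0.05-day steps, a loop of network hemodynamics, oxygen and
growth-factor (GF) transport, stochastic sprouting with directed tip
growth, tension-driven vessel migration, diameter adaptation, and
pruning. The state is a graph of straight cylindrical segments with
continuous (off-lattice) node coordinates inside a hexagonal prism
(side 150 um, height 500 um) with in-plane periodic boundary
conditions: the prism tiles the cortical layer, and every geometric
query (lengths, distances, sensing cones, field kernels) uses the
minimal-image convention of the triangular lattice whose Voronoi cell
is the hexagon. z runs from the pial surface (z = 0) into the tissue.

The initial condition is a pial vessel spanning the top face between
pressure boundaries at 100 and 20 mmHg, containing a narrow
fixed-resistance inlet stub (7 um x 35 um) representing upstream pial
arterioles, plus two 400-um sprouts perpendicular to the surface (the
future penetrating arteriole and venule). The adaptable pial portion's
initial diameter, which no observable pins directly, is calibrated
once so the initial flow is 40.2 nl/min (8.9612 um with the in-vivo
viscosity law at inlet discharge hematocrit 0.45 and plasma viscosity
1 cP).

## Hemodynamics

Segment resistance is Poiseuille with the empirical apparent viscosity
of blood in narrow tubes (diameter- and hematocrit-dependent). Two
published parameterizations are implemented: the in-vivo law (with the
endothelial-layer term, the default) and the bare in-vitro glass-tube
law; the choice is a configuration flag recorded with every run. Nodal
pressures solve the conservation system with Dirichlet boundary nodes
(direct sparse solve). Red cells partition unequally at diverging
bifurcations according to the empirical logit law in the feeding
diameter and hematocrit; at junctions with three or more outflows the
hematocrit passes unchanged (such nodes are rare and transient).
Because viscosities depend on hematocrits, which depend on the flow
split, pressures and hematocrits are iterated to a joint fixed point
(successive substitution, under-relaxation 0.5 on hematocrits,
tolerance 1e-6, cap 200 iterations), followed by one exact
propagation pass so that nodal red-cell balances close to machine
precision. Segments with |Q| below 1e-10 nl/min keep their previous
hematocrit and are excluded from oxygen exchange.

## Oxygen transport

Tissue P_O2 obeys K lap(P) = M(P) with Krogh diffusion constant
K = 9.375e-10 cm^3 O2 cm^-1 s^-1 mmHg^-1 and Michaelis-Menten
consumption (M0 = 7.5 cm^3 O2/100 cm^3/min, half-max at 10.5 mmHg).
Blood carries f(P_b) = Q [H_D C0 S(P_b) + alpha_eff P_b] with Hill
saturation (P50 = 40.2 mmHg, n = 2.59). The coupled fields are solved
by a Green's-function method: conducting segments are discretized into
~20-um subsegments acting as line sources (self-interaction evaluated
at the wall radius by the finite-line formula), tissue points are
point sinks with a sphere-equivalent self-term, and all kernel sums
include the six nearest periodic in-plane images plus mirror images
across the top and bottom faces.

Three numerical choices matter:

* **No-flux slab faces.** Mirrors at z = 0 and z = height make the
  slab faces impermeable. With free faces, the surface-hugging initial
  vessel loses over a tenth of its oxygen flux to the empty half-space
  and the global balance cannot close; with mirrors the balance audit
  passes at the worst-case initial state. The free-face variant
  remains available as a flag.
* **Far-field closure.** Free-space kernels alone conserve nothing: a
  network in non-consuming tissue would still "lose" oxygen to
  infinity. The fields therefore carry a uniform additive constant
  P_inf, determined together with the source strengths by a bordered
  linear system that enforces total source = total sink exactly. This
  reproduces the correct limits (zero consumption implies zero
  extraction and a uniform tissue field at the blood value) and makes
  the global oxygen balance exact by construction.
* **Implicit coupling.** Given sink strengths, the wall-matching
  condition (blood P_O2 minus the lumped intravascular drop equals the
  superposed tissue field at the wall; Nusselt-type coefficient 3) is
  linear in the source strengths and solved directly (LU of the
  bordered matrix, with the linearized blood-depletion slope dP_b/dq
  on the diagonal so low-flow segments cannot overdraw their supply).
  The Michaelis-Menten sinks are solved by damped Newton-Krylov (GMRES
  on J = I + diag(M') H with a diagonal preconditioner), and an outer
  Picard loop couples both to the convective marching of blood P_O2
  along the flow (P_O2 continuous across junctions, which conserves
  oxygen exactly given red-cell conservation). Outer tolerance 1e-3
  mmHg; in transitional states with steep consumption gradients the
  loop may stagnate at a few mmHg and is then accepted and flagged —
  the final consistency pass keeps the balance exact regardless.

## Growth factor

GF is released at tissue points at K_GF C_GF0 / (1 + (P/P_GF)^N_GF),
diffuses and degrades linearly: the screened kernel
exp(-r/L_GF)/(4 pi D_GF r) with L_GF = 50 um, superposed over the
same image set. Concentrations are evaluated anywhere (segment
midpoints, sprout tips) and clamped to [0, C_GF0]; the gradient is the
analytic kernel derivative, not a grid difference. Vessel uptake of GF
is neglected in the tissue field.

## Angiogenesis

Each segment (sprouts included, the fixed inlet stub excluded) draws a
sprout with probability k_p l dt (C_GF - C_th)/(C_th50 + C_GF - C_th),
evaluated at the segment midpoint, capped at 1. The attachment point
is uniform on the parent; within 10 um of an endpoint it snaps to that
node, and draws landing on boundary nodes or existing branch points
are suppressed. New tips start in a uniformly random direction
perpendicular to the parent and are laid down with a 5-um initial
stub. Per step a tip rotates its direction by a random angle
(N(0, sigma_s), axis uniform in the normal plane), adds the homing
vector (line-integrated attraction over segments in a forward cone of
reach 25 um and half-angle 60 degrees, with weights vanishing at both
cone boundaries; 8-point Gauss quadrature per segment; the tip's own
chain excluded) and the GF-gradient term, renormalizes, and advances
V_g dt = 16.65 um in 5-um increments, connecting to the closest point
of any foreign segment that comes within 5 um (snapping to an existing
node where the split would create a segment shorter than 5 um; at most
one connection per tip per step). Sprout chains that join the
boundary-to-boundary flow core become flowing at diameter 8 um.

## Remodeling

Node migration uses the normalized tension imbalance
f_t = (sum D_i e_i)(sum D_i)/(sum l_i D_i); above the threshold
lambda_t the node moves at v_max (1 - lambda_t/|f_t|) along f_t (the
printed per-step maximum of 4 um). The literal formula
v = v_max f_t (1 - lambda_t/|f_t|) is unbounded in |f_t| and
contradicts its stated saturation at v_max; the saturating form is
implemented. Boundary nodes, nodes of the fixed inlet stub and blind
ends do not migrate.

The convected signal integrates dJ_GF/ds = kappa_GF C_GF downstream
from zero at inflows, summing at converging nodes and splitting in
proportion to volumetric flow at diverging nodes (a convected quantity
follows the blood; the split rule is not otherwise determined);
C_GFv = J_GF(mid)/(Q + Q_ref) and S_m = C_GFv/(C_GFv + 200). The
conducted signal integrates dJ_c/ds = S_m - J_c/L_c upstream from zero
at outflows with the exact exponential one-segment update. At
junctions the conducted quantity behaves as a wall signal flux
F = J_c D: where conduction paths merge (a flow-diverging bifurcation)
the incoming signals are weighted by their diameters and summed into
the feeding vessel, so the metabolic need of the entire downstream bed
accumulates along the supplying tree — the defining property of
conducted responses; where one conduction path serves several upstream
vessels the flux divides in proportion to their diameters. The
alternative normalized (diameter-weighted mean) reading of the merge
rule was tried first and discarded: it dilutes the signal at every
junction, so feeding vessels never learn about more than a local
average of their bed, and the selective pressure that should favor
penetrating vessels over the surface shunt disappears.
S_c = S_c_max J_c/(J_c + 500) at the midpoint. Flowing, non-fixed
segments then update D by D S_tot dt/T with
S_tot = ln(tau_w + tau_ref) - ln tau_e(P) + k_m (S_m + S_c)/D - k_s,
natural logarithms, tau_e(P) = 14 + 86 P^5/(P^5 + 36^5) and P the mean
endpoint pressure. No floor or cap is applied to D: pruning removes
collapse, and the 1/D weighting of the metabolic term self-limits
growth.

Pruning removes flowing segments below 3 um (the red-cell passage
minimum), then every segment no longer on any simple
inflow-to-outflow path (computed exactly by peeling pendant
biconnected blocks of the segment graph), then sprout chains detached
from the surviving network.

## Parameters

All reference values are carried by `Parameters` with units documented
per field; the defaults are the published calibration for this tissue
(e.g. C_th = 0.7, k_p = 0.22 um^-1 day^-1, V_g = 333 um/day, k_m = 18,
k_s = 1.8, S_c_max = 1, L_c = 1.73 cm). Derived per-step magnitudes:
sprout advance 16.65 um, migration cap 4 um, and a sprouting
probability below 0.22 per step for a 20-um segment. Configuration
files are flat YAML with these canonical names; unknown keys are
rejected by name. Values the sources leave open and this package
fixes: inlet discharge hematocrit 0.45; plasma viscosity 1 cP;
dimensional reading of k_GF and k_V as um (required for Eq-level
consistency of the steering sum); node-merge tolerance 10 um.

## Stability, runs and problem sizes

A run is 200 steps (10 days) with early stopping once no tissue point
has C_GF above C_th, the topology is unchanged, and all relative
diameter changes stay below 1e-4 for 10 consecutive steps. Runaway
diameter growth or a solver failure terminates the run with a labeled
failure record — loss of stability is a reported outcome, not an
error.

At reference scale (3675 tissue points, ~1000-2000 segments at the
growth peak) a full run takes hours on one CPU; the kernel matrices
and their factorizations dominate. The test suite and the acceptance
script therefore run a scaled-down configuration — hexagon side
100 um (1625 tissue points), same height, spacing and reference
parameters, single seed, horizon up to 7 simulated days with early
stopping — which preserves the qualitative sequence (initial
near-total hypoxia, first A-V connections, pruning of the pial shunt,
oxygenation) at roughly a fifth of the cost. Quantities reported from
the scaled run are emergent outcomes of that smaller domain, not
re-tuned values; the full-scale protocol (8 seeds, 10 days averaged)
is available through `angiosim.run`/the CLI.

## Known limitations

The fate of the initial surface A-V shunt is delicately balanced in
this model: whether it regresses (rerouting flow through the
penetrating vessels) or settles into a stable high-flow state depends
on the sign of its total adaptive stimulus in the very first steps,
which in turn depends on details the sources leave open — the
viscosity parameterization, the plasma viscosity, and the calibrated
initial pial diameter, which together set the initial wall shear
against the expected-shear correlation within about ten percent of the
neutral point. Under this package's defaults the calibrated initial
state sits slightly on the growth side, and in the runs exercised by
the test suite the shunt persists and the network reaches a
high-flow, partially hypoxic quasi-steady state rather than the fully
oxygenated pruned-shunt architecture. The corresponding dynamic
acceptance checks fail honestly rather than being relaxed. The
oxygen solver may also stagnate at a few mmHg (flagged on the returned
state) in transitional networks whose low-flow pathways are near their
convective supply limit; segments below 0.01 nl/min are excluded from
oxygen exchange outright, since their whole convective flux is
negligible and their inclusion makes the source-matching system
ill-posed.

## What the model does not include

Pulsatility, vessel compliance, red-cell tracking, tip/stalk cell
biology beyond the homing cone, GF convection by interstitial flow,
myoglobin-facilitated transport, sprout retraction (unconnected
sprouts persist unless their parent is pruned), curved segment
primitives (curvature emerges from chains of straight segments), and
connections to vasculature below the slab. The tissue lattice carries
no anatomy: passing tests demonstrates internal consistency and
faithfulness to the stated mechanisms, not agreement with any
particular animal's microangioarchitecture.
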