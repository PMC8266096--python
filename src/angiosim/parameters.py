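"""Model parameters: reference values and run-level settings.

The reference set reproduces the published calibration for the mouse
cerebral cortex. Units are stated per field; see :mod:`angiosim.units`
for the working-unit conventions. Growth-factor (GF) concentrations are
dimensionless, scaled so the maximal level ``c_gf0`` equals 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict

__all__ = ["Parameters"]


@dataclass
class Parameters:
    # --- blood oxygen -------------------------------------------------
    #: maximal RBC oxygen concentration, cm^3 O2 / cm^3
    c0: float = 0.516
    #: effective oxygen solubility in blood, cm^3 O2 cm^-3 mmHg^-1
    alpha_eff: float = 3.1e-5
    #: Hill equation half-saturation pressure, mmHg
    p50: float = 40.2
    #: Hill equation exponent
    hill_n: float = 2.59

    # --- tissue oxygen ------------------------------------------------
    #: Krogh diffusion constant D_O2 * alpha, cm^3 O2 cm^-1 s^-1 mmHg^-1
    krogh_k: float = 9.375e-10
    #: maximal oxygen consumption rate M0, cm^3 O2 (100 cm^3)^-1 min^-1
    m0: float = 7.5
    #: P_O2 at half-maximal consumption, mmHg
    p_crit: float = 10.5

    # --- growth factor ------------------------------------------------
    #: GF diffusivity, cm^2/s
    d_gf: float = 2.0e-7
    #: tissue GF degradation rate constant, 1/s
    k_gf_deg: float = 8.0e-3
    #: maximal GF concentration (dimensionless scale)
    c_gf0: float = 1.0
    #: tissue P_O2 at half-maximal GF release, mmHg
    p_gf: float = 40.0
    #: Hill exponent for GF release
    n_gf: float = 2.5

    # --- angiogenesis ---------------------------------------------------
    #: time step, days
    dt: float = 0.05
    #: diameter of new sprouts, um
    d_sprout: float = 8.0
    #: threshold GF concentration for sprouting
    c_th: float = 0.7
    #: half-saturation constant in the sprouting probability
    c_th50: float = 0.5
    #: maximal sprout formation probability, um^-1 day^-1
    k_p: float = 0.22
    #: sprout growth speed, um/day
    v_g: float = 333.0
    #: directional sensitivity to the GF gradient, um
    k_gf_dir: float = 20.0
    #: attraction (homing) sensitivity to nearby vessels, um
    k_v: float = 1.0
    #: maximum vessel sensing distance, um
    r_max: float = 25.0
    #: maximum vessel sensing half-angle, rad
    theta_max: float = math.pi / 3.0
    #: variance of the per-step growth-direction randomization, rad^2
    sigma_s: float = 0.05

    # --- tension-induced node migration --------------------------------
    #: dimensionless force threshold for migration
    lambda_t: float = 0.25
    #: maximum migration speed, um/day
    v_max: float = 80.0

    # --- structural adaptation -----------------------------------------
    #: adaptation time scale, days
    t_adapt: float = 1.0
    #: small reference wall shear stress, dyn/cm^2
    tau_ref: float = 0.01
    #: metabolic sensitivity
    k_m: float = 18.0
    #: shrinking tendency
    k_s: float = 1.8
    #: vessel wall permeability to GF (arbitrary units)
    kappa_gf: float = 1.0
    #: small reference flow to avoid singularity, nl/min
    q_ref: float = 0.1
    #: convected-response half-saturation constant
    c_gf50v: float = 200.0
    #: conducted-response half-saturation constant, um
    j_c50: float = 500.0
    #: conducted-response decay length, um (1.73 cm)
    l_c: float = 17300.0
    #: relative strength of the conducted response
    s_c_max: float = 1.0

    # --- boundary conditions and design defaults ------------------------
    #: inflow boundary pressure, mmHg
    inflow_pressure: float = 100.0
    #: outflow boundary pressure, mmHg
    outflow_pressure: float = 20.0
    #: P_O2 of inflowing blood, mmHg
    inflow_po2: float = 100.0
    #: discharge hematocrit of inflowing blood
    inlet_hd: float = 0.45
    #: initial diameter of the adaptable pial vessel portion, um
    #: (calibrated so the initial network flow is 40.2 nl/min)
    pial_vessel_diameter: float = 8.9612
    #: fixed-resistance inlet segment: diameter and length, um
    fixed_segment_diameter: float = 7.0
    fixed_segment_length: float = 35.0
    #: pruning diameter threshold (red-cell passage minimum), um
    pruning_diameter: float = 3.0
    #: pressure scale of the expected-shear correlation, mmHg
    p_tau: float = 36.0
    #: expected-shear baseline and amplitude, dyn/cm^2
    tau_e_base: float = 14.0
    tau_e_amp: float = 86.0
    #: hypoxia threshold for tissue points, mmHg
    hypoxia_threshold: float = 20.0
    #: simulated duration, days
    sim_duration: float = 10.0

    # --- discretization and numerics -------------------------------------
    #: target subsegment length for transport and network granularity, um
    seg_target_length: float = 20.0
    #: tissue grid spacing, um
    grid_spacing: float = 20.0
    #: initial sprout length, um
    sprout_initial_length: float = 400.0
    #: node merge tolerance / sprout snap distance, um
    node_merge_tol: float = 10.0
    #: tip connection distance and growth increment, um
    connect_distance: float = 5.0
    growth_increment: float = 5.0
    #: plasma viscosity, cP
    plasma_viscosity: float = 1.0
    #: viscosity law variant: "in_vivo" (with the endothelial surface
    #: layer; keeps the narrow inlet stub an effective flow brake) or
    #: the bare glass-tube "in_vitro" law
    viscosity_law: str = "in_vivo"
    #: rings of in-plane periodic images used in field kernels (0 or 1)
    image_rings: int = 1
    #: mirror transport sources across the top and bottom faces
    #: (no-flux boundaries for the slab); free faces if False
    z_mirror: bool = True
    #: domain geometry, um
    hex_side: float = 150.0
    hex_height: float = 500.0

    def __post_init__(self) -> None:
        positive = [
            "c0", "alpha_eff", "p50", "hill_n", "krogh_k", "m0", "p_crit",
            "d_gf", "k_gf_deg", "c_gf0", "p_gf", "n_gf", "dt", "d_sprout",
            "c_th", "c_th50", "k_p", "v_g", "r_max", "theta_max", "t_adapt",
            "tau_ref", "kappa_gf", "q_ref", "c_gf50v", "j_c50", "l_c",
            "lambda_t", "v_max", "pial_vessel_diameter",
            "fixed_segment_diameter", "fixed_segment_length",
            "pruning_diameter", "p_tau", "hypoxia_threshold", "sim_duration",
            "seg_target_length", "grid_spacing", "sprout_initial_length",
            "node_merge_tol", "connect_distance", "growth_increment",
            "plasma_viscosity", "hex_side", "hex_height",
        ]
        for name in positive:
            if getattr(self, name) <= 0.0:
                raise ValueError(f"parameter {name!r} must be positive")
        for name in ("sigma_s", "k_gf_dir", "k_v", "k_m", "k_s", "s_c_max"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"parameter {name!r} must be non-negative")
        if not 0.0 <= self.inlet_hd <= 1.0:
            raise ValueError("inlet_hd must lie in [0, 1]")
        if self.viscosity_law not in ("in_vivo", "in_vitro"):
            raise ValueError("viscosity_law must be 'in_vivo' or 'in_vitro'")
        if self.image_rings not in (0, 1):
            raise ValueError("image_rings must be 0 or 1")
        if not math.pi > self.theta_max > 0.0:
            raise ValueError("theta_max must lie in (0, pi)")

    # -- derived quantities ----------------------------------------------

    @property
    def gf_decay_length(self) -> float:
        """GF diffusion-degradation length sqrt(D_GF/K_GF), um."""
        return math.sqrt(self.d_gf / self.k_gf_deg) * 1.0e4

    @property
    def n_steps(self) -> int:
        """Number of time steps in the default run."""
        return int(round(self.sim_duration / self.dt))

    def replace(self, **kwargs) -> "Parameters":
        """Return a copy with the given fields replaced."""
        d = asdict(self)
        d.update(kwargs)
        return Parameters(**d)

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]
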