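"""Quasi-steady oxygen and growth-factor transport.

Oxygen: blood P_O2 is convected along flowing segments and released to
tissue; the tissue field satisfies a diffusion equation with
Michaelis-Menten consumption. Both are solved jointly by a Green's
function method: vessel subsegments act as discrete sources and tissue
points as discrete sinks, whose free-space kernel fields superpose. An
iterative algorithm adjusts source strengths until intravascular and
extravascular P_O2 match at each subsegment, including a lumped
intravascular resistance to radial diffusion, while sink strengths
relax to the consumption rate at the local tissue P_O2.

Growth factor (GF): released in hypoxic tissue, diffusing with linear
degradation, which gives a screened kernel exp(-r/L_GF)/(4 pi D r) with
decay length L_GF = sqrt(D_GF/K_GF). The field and its analytic
gradient are evaluated by superposition over tissue release sources.
GF uptake by vessels is neglected.

In-plane hexagonal periodicity is approximated by adding the six
nearest-neighbor image cells to every kernel sum; the top and bottom
slab faces are no-flux boundaries by default (mirror images), with
free faces available as a configuration flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla
from scipy.linalg import lu_factor, lu_solve

from .geometry import HexDomain
from .hemodynamics import Q_FLOOR
from .network import VesselNetwork
from .parameters import Parameters

__all__ = [
    "hill_saturation", "consumption_rate", "gf_release_rate",
    "solve_oxygen_field", "solve_gf_field",
    "BloodOxygenState", "TissueOxygenState", "GFState", "FieldCache",
]

#: conversion of the Krogh diffusion constant from
#: cm^3O2 cm^-1 s^-1 mmHg^-1 to cm^3O2 um^-1 min^-1 mmHg^-1
_KROGH_TO_UM_MIN = 60.0e-4

#: dimensionless Nusselt-type coefficient of the lumped intravascular
#: resistance to radial oxygen diffusion
NUSSELT = 3.0

#: nl/min -> cm^3/min
_NL = 1.0e-6

#: segments carrying less flow than this (nl/min) exchange no oxygen:
#: their entire convective flux is negligible against network totals,
#: and including them makes the source-matching system ill-posed
Q_EXCHANGE_MIN = 0.01


def hill_saturation(p_b, params: Parameters):
    """Oxyhemoglobin saturation S(P_b) = P^n / (P^n + P50^n)."""
    p = np.asarray(p_b, dtype=float)
    if np.any(p < 0.0):
        raise ValueError("blood P_O2 must be non-negative")
    pn = np.power(p, params.hill_n)
    return pn / (pn + params.p50 ** params.hill_n)


def _hill_slope(p_b, params: Parameters):
    p = np.maximum(np.asarray(p_b, dtype=float), 1e-9)
    k = params.p50 ** params.hill_n
    pn = np.power(p, params.hill_n)
    return params.hill_n * np.power(p, params.hill_n - 1.0) * k / (pn + k) ** 2


def consumption_rate(po2, params: Parameters):
    """Michaelis-Menten consumption M(P) = M0 P / (P_c + P).

    Input mmHg; output in cm^3 O2 (100 cm^3)^-1 min^-1. Negative P
    (possible transiently in the superposed field) consumes nothing.
    """
    p = np.maximum(np.asarray(po2, dtype=float), 0.0)
    return params.m0 * p / (params.p_crit + p)


def gf_release_rate(po2, params: Parameters):
    """GF release rate M_GF = K_GF C_GF0 / (1 + (P/P_GF)^N_GF), in 1/s."""
    p = np.maximum(np.asarray(po2, dtype=float), 0.0)
    return params.k_gf_deg * params.c_gf0 / (
        1.0 + np.power(p / params.p_gf, params.n_gf))


def _blood_content(p, hd, params: Parameters):
    """O2 content per unit blood volume, cm^3O2/cm^3: Hd C0 S(P) + a_eff P."""
    return hd * params.c0 * hill_saturation(p, params) + params.alpha_eff * p


def _invert_content_scalar(target: float, hd: float, params: Parameters,
                           p_hi: float = 200.0) -> float:
    """Scalar inversion of the blood O2 content (hot path in marching)."""
    if target <= 0.0:
        return 0.0
    c0hd = hd * params.c0
    alpha = params.alpha_eff
    n = params.hill_n
    p50n = params.p50 ** n
    lo, hi = 0.0, p_hi
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        pn = mid ** n
        if c0hd * pn / (pn + p50n) + alpha * mid > target:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _invert_content(target, hd, params: Parameters, p_hi: float = 200.0):
    """Solve Hd C0 S(P) + a_eff P = target for P >= 0 (vector bisection)."""
    target = np.asarray(target, dtype=float)
    hd = np.broadcast_to(np.asarray(hd, dtype=float), target.shape)
    lo = np.zeros_like(target)
    hi = np.full_like(target, p_hi)
    neg = target <= 0.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        val = _blood_content(mid, hd, params)
        high = val > target
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
    p = 0.5 * (lo + hi)
    return np.where(neg, 0.0, p)


# ---------------------------------------------------------------------------
# kernel builders


def _image_offsets(domain: HexDomain | None, rings: int) -> np.ndarray:
    if domain is None or rings == 0:
        return np.zeros((1, 3))
    return domain.image_offsets()


def _mirror_variants(sources: np.ndarray, domain: HexDomain | None,
                     params: Parameters) -> list[np.ndarray]:
    """Source set plus its reflections across the top/bottom faces.

    Reflections impose no-flux (mirror) boundaries at z = 0 and
    z = height; sources lying exactly on a face coincide with their
    image, which correctly doubles their half-space field.
    """
    variants = [sources]
    if domain is not None and params.z_mirror:
        low = sources.copy()
        low[:, 2] = -low[:, 2]
        high = sources.copy()
        high[:, 2] = 2.0 * domain.height - high[:, 2]
        variants += [low, high]
    return variants


def _folded_kernel(targets: np.ndarray, sources: np.ndarray, kern,
                   offsets: np.ndarray, r_floor, domain: HexDomain | None,
                   params: Parameters) -> np.ndarray:
    """Kernel matrix summed over periodic images and z-mirrors."""
    out = None
    for variant in _mirror_variants(sources, domain, params):
        g = _kernel_sum(targets, variant, kern, offsets, r_floor)
        out = g if out is None else out + g
    return out


def _kernel_sum(targets: np.ndarray, sources: np.ndarray,
                kern, offsets: np.ndarray, r_floor,
                chunk: int = 512) -> np.ndarray:
    """Sum kern(|t - (s + off)|) over image offsets -> (n_t, n_s) matrix.

    ``r_floor`` may be scalar or per-source (vessel radius clamp).
    """
    n_t, n_s = len(targets), len(sources)
    out = np.zeros((n_t, n_s))
    r_floor = np.broadcast_to(np.asarray(r_floor, dtype=float), (n_s,))
    for start in range(0, n_t, chunk):
        t = targets[start:start + chunk]
        acc = np.zeros((len(t), n_s))
        for off in offsets:
            d = t[:, None, :] - (sources[None, :, :] + off[None, None, :])
            r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
            np.maximum(r, r_floor[None, :], out=r)
            acc += kern(r)
        out[start:start + chunk] = acc
    return out


@dataclass
class FieldCache:
    """Precomputed tissue-tissue kernel matrices for a fixed grid."""
    g_tt_o2: np.ndarray = None
    g_tt_gf: np.ndarray = None
    n_points: int = 0


def _oxygen_kernel(params: Parameters):
    k = params.krogh_k * _KROGH_TO_UM_MIN

    def kern(r):
        return 1.0 / (4.0 * np.pi * k * r)

    return kern, k


def _tissue_self_g(point_volume: float, k: float) -> float:
    """Self-interaction of a cubic tissue source, sphere-equivalent."""
    a = (3.0 * point_volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    return 3.0 / (8.0 * np.pi * k * a)


def _vessel_self_g(length: np.ndarray, diameter: np.ndarray,
                   k: float) -> np.ndarray:
    """Field of a finite-line source at its own wall (r = D/2)."""
    ratio = length / diameter
    return np.arcsinh(ratio) / (2.0 * np.pi * k * length)


# ---------------------------------------------------------------------------
# oxygen solver


@dataclass
class BloodOxygenState:
    """Per-subsegment intravascular oxygen state."""
    seg_id: np.ndarray        # parent segment id
    midpoints: np.ndarray     # (n, 3) um
    lengths: np.ndarray       # um
    diameters: np.ndarray     # um
    flows: np.ndarray         # nl/min, positive (flow-oriented)
    hd: np.ndarray
    po2: np.ndarray           # blood P_O2 at subsegment midpoint, mmHg
    saturation: np.ndarray
    source: np.ndarray        # O2 delivered to tissue, cm^3O2/min
    inflow_flux: float = 0.0  # total convective O2 inflow, cm^3O2/min
    outflow_flux: float = 0.0
    outflow_po2: dict = field(default_factory=dict)  # node id -> mmHg

    def mean_po2(self) -> float:
        """Length-weighted mean intravascular P_O2 (mmHg)."""
        w = self.lengths
        return float(np.sum(w * self.po2) / np.sum(w)) if len(w) else np.nan

    def sd_po2(self) -> float:
        w = self.lengths
        if not len(w):
            return np.nan
        m = self.mean_po2()
        return float(np.sqrt(np.sum(w * (self.po2 - m) ** 2) / np.sum(w)))

    def segment_mean_po2(self) -> dict[int, float]:
        """Length-weighted mean blood P_O2 per parent segment."""
        acc: dict[int, list[float]] = {}
        for sid, l, p in zip(self.seg_id, self.lengths, self.po2):
            acc.setdefault(int(sid), [0.0, 0.0])
            acc[int(sid)][0] += l * p
            acc[int(sid)][1] += l
        return {sid: v[0] / v[1] for sid, v in acc.items()}


@dataclass
class TissueOxygenState:
    po2: np.ndarray           # mmHg, at tissue points (floored at 0)
    consumption: np.ndarray   # cm^3O2 (100cm^3)^-1 min^-1
    total_consumption: float  # cm^3O2/min
    p_inf: float = 0.0        # uniform far-field level, mmHg
    converged: bool = True
    iterations: int = 0
    residual: float = 0.0


def _build_subsegments(net: VesselNetwork, params: Parameters):
    """Flow-oriented subsegment arrays plus per-segment chain indices."""
    segs = [s for s in net.conducting_segments()
            if abs(s.flow) > Q_EXCHANGE_MIN]
    mids, lens, dias, flows, hds, sids = [], [], [], [], [], []
    chains: dict[int, list[int]] = {}
    up_node: dict[int, int] = {}
    down_node: dict[int, int] = {}
    for s in segs:
        length = net.segment_length(s)
        n_k = max(1, int(np.ceil(length / params.seg_target_length)))
        a = net.nodes[s.from_node].position
        vec = net.segment_vector(s)
        ts = (np.arange(n_k) + 0.5) / n_k
        if s.flow < 0.0:
            ts = ts[::-1]
            up_node[s.id], down_node[s.id] = s.to_node, s.from_node
        else:
            up_node[s.id], down_node[s.id] = s.from_node, s.to_node
        idx0 = len(mids)
        for t in ts:
            mids.append(net.domain.wrap(a + t * vec))
            lens.append(length / n_k)
            dias.append(s.diameter)
            flows.append(abs(s.flow))
            hds.append(s.hd)
            sids.append(s.id)
        chains[s.id] = list(range(idx0, idx0 + n_k))
    if not mids:
        return None
    return dict(
        midpoints=np.array(mids), lengths=np.array(lens),
        diameters=np.array(dias), flows=np.array(flows),
        hd=np.array(hds), seg_id=np.array(sids, dtype=int),
        chains=chains, up_node=up_node, down_node=down_node, segs=segs,
    )


def _influence_rows(net: VesselNetwork, sub) -> np.ndarray:
    """Convective influence matrix R: R[k, j] is the fraction of
    subsegment j's oxygen removal that has passed subsegment k's
    midpoint (1 for j fully upstream on k's supply path, 0.5 for
    j = k, diluted by flow splits at bifurcations). Depends only on
    topology and flows, so it is built once per field solve and used
    to linearize the blood-depletion feedback dP_b/dq exactly.
    """
    n = len(sub["lengths"])
    segs = {s.id: s for s in sub["segs"]}
    out_by_node: dict[int, list[int]] = {}
    for sid in segs:
        out_by_node.setdefault(sub["up_node"][sid], []).append(sid)
    order = sorted(
        {nid for sid in segs for nid in (sub["up_node"][sid],
                                         sub["down_node"][sid])},
        key=lambda nid: -net.nodes[nid].pressure)
    r_mid = np.zeros((n, n))
    node_row: dict[int, np.ndarray] = {}
    node_q: dict[int, float] = {}
    for nid in order:
        outs = out_by_node.get(nid, [])
        if not outs:
            continue
        row = node_row.get(nid)
        if row is None or net.nodes[nid].boundary_kind == "inflow_pressure":
            row = np.zeros(n)
        else:
            row = row / max(node_q.get(nid, 0.0), 1e-300)
        for sid in outs:
            chain = sub["chains"][sid]
            acc = row.copy()
            for k in chain:
                r_mid[k] = acc
                r_mid[k, k] = 0.5
                acc = acc.copy()
                acc[k] = 1.0
            down = sub["down_node"][sid]
            q_seg = sub["flows"][chain[0]]
            if down in node_row:
                node_row[down] = node_row[down] + q_seg * acc
                node_q[down] = node_q[down] + q_seg
            else:
                node_row[down] = q_seg * acc
                node_q[down] = q_seg
    return r_mid


def _march_blood(net: VesselNetwork, sub, q_v: np.ndarray,
                 params: Parameters):
    """Propagate blood P_O2 along flow given subsegment source strengths.

    P_O2 is continuous across nodes: at each junction the node P solves
    total O2 flux conservation with the downstream segments' own
    hematocrits, which conserves O2 exactly because RBC flux and blood
    flow are conserved. Returns midpoint P_b, f' slopes and boundary
    flux bookkeeping.
    """
    c0 = params.c0
    alpha = params.alpha_eff
    n_hill = params.hill_n
    p50n = params.p50 ** n_hill

    def content(p: float, hd: float) -> float:
        pn = p ** n_hill if p > 0.0 else 0.0
        return hd * c0 * pn / (pn + p50n) + alpha * p if p > 0.0 else 0.0

    segs = {s.id: s for s in sub["segs"]}
    f_acc: dict[int, float] = {}
    out_by_node: dict[int, list[int]] = {}
    for sid in segs:
        out_by_node.setdefault(sub["up_node"][sid], []).append(sid)
    order = sorted(
        {n for sid in segs for n in (sub["up_node"][sid],
                                     sub["down_node"][sid])},
        key=lambda nid: -net.nodes[nid].pressure)
    flows = sub["flows"]
    hds = sub["hd"]
    chains = sub["chains"]
    p_mid = np.zeros(len(sub["lengths"]))
    inflow_flux = 0.0
    outflow_flux = 0.0
    outflow_po2: dict[int, float] = {}
    for nid in order:
        node = net.nodes[nid]
        outs = out_by_node.get(nid, [])
        if not outs:
            if node.boundary_kind == "outflow_pressure":
                f_out = f_acc.get(nid, 0.0)
                outflow_flux += f_out
                q_tot = sum(_NL * flows[chains[sid][0]] for sid in segs
                            if sub["down_node"][sid] == nid)
                if q_tot > 0.0:
                    hd_eff = sum(
                        _NL * flows[chains[sid][0]] * hds[chains[sid][0]]
                        for sid in segs
                        if sub["down_node"][sid] == nid) / q_tot
                    outflow_po2[nid] = _invert_content_scalar(
                        f_out / q_tot, hd_eff, params)
            continue
        q_out = [_NL * flows[chains[sid][0]] for sid in outs]
        hd_out = [hds[chains[sid][0]] for sid in outs]
        if node.boundary_kind == "inflow_pressure":
            p_node = node.boundary_po2
            f_in = sum(q * content(p_node, h)
                       for q, h in zip(q_out, hd_out))
            inflow_flux += f_in
        else:
            f_in = f_acc.get(nid, 0.0)
            if f_in <= 0.0:
                p_node = 0.0
            else:
                # solve sum_o Q_o c(P, Hd_o) = f_in for the node P
                lo, hi = 0.0, 200.0
                for _ in range(50):
                    mid = 0.5 * (lo + hi)
                    if sum(q * content(mid, h)
                           for q, h in zip(q_out, hd_out)) > f_in:
                        hi = mid
                    else:
                        lo = mid
                p_node = 0.5 * (lo + hi)
        for sid, q_seg, hd_seg in zip(outs, q_out, hd_out):
            f = q_seg * content(p_node, hd_seg)
            for k in chains[sid]:
                f_m = f - 0.5 * q_v[k]
                p_mid[k] = _invert_content_scalar(f_m / q_seg, hd_seg,
                                                  params)
                f = max(f - q_v[k], 0.0)
            f_acc[sub["down_node"][sid]] = f_acc.get(
                sub["down_node"][sid], 0.0) + f
    # slope of midpoint P wrt its own source strength (for the update)
    q_cm3 = _NL * flows
    dcdp = (hds * c0 * _hill_slope(p_mid, params) + alpha)
    slope = 0.5 / (q_cm3 * dcdp)
    return p_mid, slope, inflow_flux, outflow_flux, outflow_po2


def solve_oxygen_field(net: VesselNetwork, tissue_points: np.ndarray,
                       point_volume: float, params: Parameters,
                       domain: HexDomain | None = None,
                       cache: FieldCache | None = None,
                       warm_sinks: np.ndarray | None = None,
                       tol: float = 1e-3, max_iter: int = 120):
    """Solve the coupled blood/tissue oxygen fields.

    Parameters
    ----------
    tissue_points
        (n, 3) tissue sample points (um); each represents ``point_volume``
        um^3 of tissue.
    domain
        If given, in-plane periodic images are included per
        ``params.image_rings``.
    cache
        Optional :class:`FieldCache`; its tissue-tissue matrix is built
        on first use and reused while the grid is unchanged.
    warm_sinks
        Initial sink strengths from a previous solve (same grid).

    Returns (BloodOxygenState, TissueOxygenState).
    """
    kern, k_o2 = _oxygen_kernel(params)
    offsets = _image_offsets(domain, params.image_rings)
    pts = np.asarray(tissue_points, dtype=float)
    n_t = len(pts)
    g_self_t = _tissue_self_g(point_volume, k_o2)

    if cache is not None and cache.g_tt_o2 is not None \
            and cache.n_points == n_t:
        g_tt = cache.g_tt_o2
    else:
        g_tt = _folded_kernel(pts, pts, kern, offsets, 1e-6, domain, params)
        np.fill_diagonal(
            g_tt, np.diagonal(g_tt) - kern(np.full(n_t, 1e-6)) + g_self_t)
        if cache is not None:
            cache.g_tt_o2 = g_tt
            cache.n_points = n_t

    sub = _build_subsegments(net, params)
    vol_factor = point_volume / 1.0e12 / 100.0  # (100 cm^3) units -> cm^3
    if sub is None:
        # no perfused vessels: tissue is anoxic in quasi-steady state
        po2 = np.zeros(n_t)
        blood = BloodOxygenState(
            seg_id=np.empty(0, int), midpoints=np.empty((0, 3)),
            lengths=np.empty(0), diameters=np.empty(0), flows=np.empty(0),
            hd=np.empty(0), po2=np.empty(0), saturation=np.empty(0),
            source=np.empty(0))
        tissue = TissueOxygenState(po2=po2,
                                   consumption=consumption_rate(po2, params),
                                   total_consumption=0.0)
        return blood, tissue

    mids = sub["midpoints"]
    n_v = len(mids)
    radius = sub["diameters"] / 2.0
    # vessel sources are clamped at their own wall radius; mirrors of
    # surface vessels double their half-space field
    g_tv = _folded_kernel(pts, mids, kern, offsets, radius, domain, params)
    g_vt = g_tv.T.copy()
    g_vv = _folded_kernel(mids, mids, kern, offsets, radius, domain, params)
    np.fill_diagonal(g_vv, np.diagonal(g_vv) - kern(radius)
                     + _vessel_self_g(sub["lengths"], sub["diameters"],
                                      k_o2))
    # lumped intravascular resistance per subsegment, mmHg/(cm^3O2/min)
    r_iv = 1.0 / (NUSSELT * np.pi * k_o2 * sub["lengths"])
    # Tissue fields carry a free additive constant P_inf (the uniform
    # far-field level), and total source strength is constrained to
    # equal total sink strength -- the finite-domain closure of the
    # free-space kernel superposition, which makes the oxygen balance
    # exact. The matching system is bordered with that constraint and
    # augmented on the diagonal with the linearized blood-depletion
    # slope dP_b/dq (without it, low-flow segments whose blood oxygen
    # the matching would overdraw make the outer iteration oscillate):
    #     [G_vv + diag(r_iv + slope)  1] [q    ]   [P_b + slope q0 + G_vt s]
    #     [          1^T              0] [P_inf] = [        sum(s)         ]
    a_aug = np.zeros((n_v + 1, n_v + 1))
    a_aug[:n_v, n_v] = 1.0
    a_aug[n_v, :n_v] = 1.0
    factor = {"lu": None}
    r_infl = _influence_rows(net, sub)

    def depletion(slope: np.ndarray) -> np.ndarray:
        """Linearized blood-depletion coupling -dP_b/dq (n x n).

        Diagonal: own-removal slope. Off-diagonal: upstream removals
        seen through the influence fractions, damped and capped -- the
        exact coupling is nonsmooth at the f >= 0 clamp and a full
        Newton step on it destabilizes the outer loop.
        """
        cap = 50.0 * float(np.max(np.diagonal(g_vv)))
        s_eff = np.minimum(slope, cap)
        dep = np.diag(s_eff)
        return dep

    def refactor(dep: np.ndarray) -> None:
        a_aug[:n_v, :n_v] = g_vv + np.diag(r_iv) + dep
        factor["lu"] = lu_factor(a_aug)

    def solve_aug(rhs_v: np.ndarray, rhs_c: float):
        sol = lu_solve(factor["lu"], np.append(rhs_v, rhs_c))
        return sol[:n_v], float(sol[n_v])

    q_v = np.zeros(n_v)
    sinks = (np.zeros(n_t) if warm_sinks is None or len(warm_sinks) != n_t
             else np.clip(warm_sinks, 0.0, params.m0 * vol_factor))
    s_cap = params.m0 * vol_factor  # consumption saturates at M0
    p_t = np.zeros(n_t)
    it = 0
    resid = np.inf
    march = None

    def h_matvec(x):
        """Sensitivity of the tissue field to the sinks, H x.

        P_t(s) is affine: P_t = b - H s with
        H x = G_tt x - (G_tv q_x + p_x), (q_x, p_x) the bordered-system
        response to sink increment x. The correction terms are the
        vessels' compensation: sinks depress wall P_O2, which raises
        source strengths and the far-field level.
        """
        q_x, p_x = solve_aug(g_vt @ x, float(np.sum(x)))
        return g_tt @ x - g_tv @ q_x - p_x

    def m_slope(p):
        """dM/dP (per mmHg), zero where the field is non-physical."""
        pc = params.p_crit
        return np.where(p > 0.0,
                        params.m0 * pc / (pc + np.maximum(p, 0.0)) ** 2,
                        0.0) * vol_factor

    # large systems amortize the LU refactor over several iterations;
    # the fixed point is independent of the (stale) linearization slope
    refactor_every = 1 if n_v <= 500 else 4
    dep_used = None
    for it in range(1, max_iter + 1):
        march = _march_blood(net, sub, q_v, params)
        p_b, slope = march[0], march[1]
        if dep_used is None or (it - 1) % refactor_every == 0:
            dep_used = depletion(slope)
            refactor(dep_used)
        rhs_lin = p_b + dep_used @ q_v
        q_0, p_0 = solve_aug(rhs_lin, 0.0)
        b = g_tv @ q_0 + p_0
        # Newton-Krylov on the tissue sinks: F(s) = s - M(b - H s) V = 0,
        # Jacobian J = I + diag(M') H applied matrix-free through GMRES
        # with a diagonal (local self-interaction) preconditioner
        g_tt_diag = np.diagonal(g_tt)
        for _ in range(12):
            p_t_new = b - h_matvec(sinks)
            f_res = sinks - consumption_rate(p_t_new, params) * vol_factor
            f_norm = float(np.max(np.abs(f_res)))
            if f_norm < 3e-4 * s_cap:
                break
            mp = m_slope(p_t_new)
            jac = spla.LinearOperator(
                (n_t, n_t), matvec=lambda x, mp=mp: x + mp * h_matvec(x))
            precon = spla.LinearOperator(
                (n_t, n_t),
                matvec=lambda x, mp=mp: x / (1.0 + mp * g_tt_diag))
            delta, info = spla.gmres(jac, -f_res, rtol=1e-4, restart=30,
                                     maxiter=3, M=precon)
            if info != 0 and not np.all(np.isfinite(delta)):
                delta = -f_res / (1.0 + mp * g_tt_diag)
            alpha = 1.0  # damped, clamped update
            for _ in range(6):
                s_try = np.clip(sinks + alpha * delta, 0.0, s_cap)
                p_try = b - h_matvec(s_try)
                f_try = s_try - consumption_rate(p_try, params) * vol_factor
                if float(np.max(np.abs(f_try))) < f_norm:
                    sinks = s_try
                    break
                alpha *= 0.5
            else:
                sinks = np.clip(sinks + 0.25 * delta, 0.0, s_cap)
        q_new, p_inf = solve_aug(rhs_lin + g_vt @ sinks,
                                 float(np.sum(sinks)))
        # damped Picard step on the sources
        q_v = q_v + 0.7 * (q_new - q_v)
        p_t_new = p_inf + g_tv @ q_v - g_tt @ sinks
        resid_prev = resid
        resid = max(float(np.max(np.abs(p_t_new - p_t))),
                    float(np.max(np.abs(q_new - q_v)))
                    * float(np.median(np.diagonal(g_vv))))
        p_t = p_t_new
        if resid < tol and it > 1:
            break
        if it > 20 and resid > 0.97 * resid_prev:
            break  # stagnated; accept and flag via the residual
    # final consistency pass: exact conservation for the converged
    # sinks, and blood bookkeeping for that source field
    march = _march_blood(net, sub, q_v, params)
    p_b, slope = march[0], march[1]
    dep = depletion(slope)
    refactor(dep)
    q_v, p_inf = solve_aug(p_b + dep @ q_v + g_vt @ sinks,
                           float(np.sum(sinks)))
    march = _march_blood(net, sub, q_v, params)
    p_t = p_inf + g_tv @ q_v - g_tt @ sinks
    p_b, _, f_in, f_out, out_po2 = march
    blood = BloodOxygenState(
        seg_id=sub["seg_id"], midpoints=mids, lengths=sub["lengths"],
        diameters=sub["diameters"], flows=sub["flows"], hd=sub["hd"],
        po2=p_b, saturation=np.asarray(hill_saturation(p_b, params)),
        source=q_v, inflow_flux=f_in, outflow_flux=f_out,
        outflow_po2=out_po2)
    po2_out = np.maximum(p_t, 0.0)
    tissue = TissueOxygenState(
        po2=po2_out, consumption=consumption_rate(p_t, params),
        total_consumption=float(np.sum(sinks)), p_inf=p_inf,
        converged=resid < tol, iterations=it, residual=resid)
    return blood, tissue


# ---------------------------------------------------------------------------
# growth factor


class GFState:
    """Screened-diffusion GF field from tissue release sources.

    Evaluable at arbitrary points; the gradient is the analytic
    derivative of the kernel superposition. Concentrations are clamped
    to [0, C_GF0] (the continuum solution obeys these bounds by the
    maximum principle; the discrete superposition can overshoot by a
    small quantization error near strong sources).
    """

    def __init__(self, source_points: np.ndarray, strengths: np.ndarray,
                 params: Parameters, point_volume: float,
                 domain: HexDomain | None = None):
        base = np.asarray(source_points, dtype=float)
        variants = _mirror_variants(base, domain, params)
        self.sources = np.vstack(variants)
        self.strengths = np.tile(np.asarray(strengths, dtype=float),
                                 len(variants))  # um^3/s
        self.params = params
        self.domain = domain
        self._d = params.d_gf * 1.0e8  # um^2/s
        self._decay = params.gf_decay_length  # um
        self._offsets = _image_offsets(domain, params.image_rings)
        a = (3.0 * point_volume / (4.0 * np.pi)) ** (1.0 / 3.0)
        x = a / self._decay
        v_sphere = 4.0 / 3.0 * np.pi * a ** 3
        self._g_self = (1.0 - np.exp(-x) * (1.0 + x)) / (
            params.k_gf_deg * v_sphere)
        self._self_radius = a

    def _kern(self, r):
        return np.exp(-r / self._decay) / (4.0 * np.pi * self._d * r)

    def concentration(self, points: np.ndarray,
                      g_matrix: np.ndarray | None = None) -> np.ndarray:
        """GF concentration at the given points (clamped to [0, C_GF0])."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if g_matrix is None:
            g_matrix = self.kernel_matrix(pts)
        c = g_matrix @ self.strengths
        return np.clip(c, 0.0, self.params.c_gf0)

    def _canonical(self, points: np.ndarray) -> np.ndarray:
        """Wrap evaluation points into the canonical periodic cell."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.domain is None:
            return pts
        return np.array([self.domain.wrap(p) for p in pts])

    def kernel_matrix(self, points: np.ndarray) -> np.ndarray:
        """(n_points, n_sources) kernel matrix, self-regularized."""
        pts = self._canonical(points)
        g = _kernel_sum(pts, self.sources, self._kern, self._offsets, 1e-6)
        # replace near-coincident entries by the sphere-average self term;
        # the kernel at the r floor is enormous, which flags coincidence
        big = self._kern(np.array([1e-6]))[0]
        g[g > 0.5 * big] = self._g_self
        return g

    def gradient(self, points: np.ndarray) -> np.ndarray:
        """Analytic gradient dC/dx at the given points, per um."""
        pts = self._canonical(points)
        out = np.zeros_like(pts)
        decay, d4pi = self._decay, 4.0 * np.pi * self._d
        for off in self._offsets:
            dvec = pts[:, None, :] - (self.sources[None, :, :]
                                      + off[None, None, :])
            r = np.sqrt(np.einsum("ijk,ijk->ij", dvec, dvec))
            mask = r > self._self_radius  # self cell contributes no gradient
            rs = np.where(mask, r, 1.0)
            coef = np.where(
                mask,
                -np.exp(-rs / decay) / d4pi * (1.0 / rs ** 2
                                               + 1.0 / (decay * rs)) / rs,
                0.0)
            out += np.einsum("ij,ijk->ik", coef * self.strengths[None, :],
                             dvec)
        return out


def solve_gf_field(tissue_po2: np.ndarray, tissue_points: np.ndarray,
                   point_volume: float, params: Parameters,
                   domain: HexDomain | None = None,
                   cache: FieldCache | None = None) -> GFState:
    """Compute the GF field from the tissue oxygen distribution.

    Release sources sit at the tissue points with strength
    M_GF(P_O2) x point volume; vessel uptake is neglected. The state's
    concentration at the tissue points themselves is cached on the
    returned object as ``at_tissue``.
    """
    pts = np.asarray(tissue_points, dtype=float)
    rates = np.asarray(gf_release_rate(tissue_po2, params))  # 1/s
    state = GFState(pts, rates * point_volume, params, point_volume, domain)
    if cache is not None and cache.g_tt_gf is not None \
            and cache.n_points == len(pts):
        g = cache.g_tt_gf
    else:
        g = state.kernel_matrix(pts)
        if cache is not None:
            cache.g_tt_gf = g
            cache.n_points = len(pts)
    state.at_tissue = state.concentration(pts, g_matrix=g)
    return state
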