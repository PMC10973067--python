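"""Reduced-order pulsatile hemodynamics on the vessel graph.

Each vessel edge is a Poiseuille resistor (R = 8 mu L / pi r^4); inlet
flows are prescribed waveforms; every outlet receives a fixed fraction of
the total instantaneous inflow given by Murray's-law splitting with
exponent n (n = 2 makes fractions proportional to outlet area); interior
flows and loop flows follow from the nodal pressure solve on the weighted
graph Laplacian; aneurysm sacs are compliant 0D chambers advanced by
implicit Euler.  Wall shear on an edge is the Poiseuille value
tau = 4 mu Q / (pi r^3); full radial velocity profiles are reconstructed
analytically from the edge flow harmonics (Womersley solution).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu
from scipy.special import jv

from .types import FlowWaveform, InvalidArgumentError, VesselNetwork


@dataclass
class FluidProperties:
    """Newtonian blood: dynamic viscosity (Pa s) and density (kg/m^3)."""

    mu: float = 0.004
    rho: float = 1055.0

    def __post_init__(self):
        if self.mu <= 0 or self.rho <= 0:
            raise InvalidArgumentError("mu and rho must be > 0")


@dataclass
class SolverConfig:
    dt: float = 0.001                 # s
    cycles: int = 3                   # last cycle is evaluated
    murray_n: float = 2.0
    murray_mode: str = "global"       # or "per_branch"
    reference_node: str | None = None
    linear_tol: float = 1e-12

    def __post_init__(self):
        if self.dt <= 0:
            raise InvalidArgumentError("dt must be > 0")
        if self.cycles < 1:
            raise InvalidArgumentError("cycles must be >= 1")
        if self.murray_n <= 0:
            raise InvalidArgumentError("Murray exponent must be > 0")
        if self.murray_mode not in ("global", "per_branch"):
            raise InvalidArgumentError("murray_mode must be 'global' or 'per_branch'")


@dataclass
class SimulationResult:
    """Signed per-edge flow and wall shear plus nodal pressures over the
    evaluated (final) cycle."""

    times: np.ndarray               # s, within the evaluated cycle
    period: float
    dt: float
    edge_ids: list
    edge_orientation: dict          # edge_id -> (tail, head)
    edge_radius_m: dict
    Q: np.ndarray                   # (E, T) m^3/s, positive tail -> head
    tau: np.ndarray                 # (E, T) Pa, signed
    node_ids: list
    P: np.ndarray                   # (V, T) Pa relative to reference node
    sac_pressure: dict = field(default_factory=dict)   # sac_id -> (T,) Pa
    sac_neck_flow: dict = field(default_factory=dict)  # sac_id -> (T,) m^3/s into sac
    conservation_residual: float = 0.0

    def edge_flow(self, edge_id) -> np.ndarray:
        return self.Q[self.edge_ids.index(edge_id)]

    def edge_tau(self, edge_id) -> np.ndarray:
        return self.tau[self.edge_ids.index(edge_id)]

    def node_pressure(self, node_id) -> np.ndarray:
        return self.P[self.node_ids.index(node_id)]


def murray_split_fractions(outlet_areas, n: float = 2.0) -> np.ndarray:
    """Outlet flow fractions r_i^n / sum r_j^n with r_i = sqrt(a_i / pi);
    for n = 2 this is exactly proportional to area.  The last fraction is
    set to 1 - sum(others) so the fractions sum to 1 exactly."""
    a = np.asarray(outlet_areas, dtype=float)
    if a.size == 0:
        raise InvalidArgumentError("outlet area list must be non-empty")
    if np.any(a <= 0):
        raise InvalidArgumentError("all outlet areas must be > 0")
    r = np.sqrt(a / np.pi)
    w = r ** n
    f = w / w.sum()
    f[-1] = 1.0 - f[:-1].sum()
    return f


def edge_resistance(radius: float, length: float,
                    fluid: FluidProperties | None = None) -> float:
    """Poiseuille resistance 8 mu L / (pi r^4), SI units (Pa s / m^3)."""
    fluid = fluid or FluidProperties()
    if radius <= 0 or length <= 0:
        raise InvalidArgumentError("radius and length must be > 0")
    return 8.0 * fluid.mu * length / (np.pi * radius ** 4)


def poiseuille_wall_shear(q: np.ndarray, radius: float,
                          fluid: FluidProperties | None = None) -> np.ndarray:
    """Signed wall shear 4 mu Q / (pi r^3) in Pa (SI inputs)."""
    fluid = fluid or FluidProperties()
    return 4.0 * fluid.mu * np.asarray(q) / (np.pi * radius ** 3)


MM = 1e-3          # mm -> m
LPS = 1e-3         # l/s -> m^3/s


def _outlet_fraction_map(network: VesselNetwork, config: SolverConfig):
    """Per-outlet fraction of the total instantaneous inflow."""
    from .network import _outlet_inlet_branch, outlet_area  # local import: cycle

    outs = network.outlets
    if not outs:
        raise InvalidArgumentError("network has no outlets")
    areas = np.array([outlet_area(network, o) for o in outs])
    if config.murray_mode == "global":
        f = murray_split_fractions(areas, config.murray_n)
        return dict(zip(outs, f)), None
    groups: dict[str, list[int]] = {}
    for i, o in enumerate(outs):
        groups.setdefault(_outlet_inlet_branch(network, o), []).append(i)
    frac = np.zeros(len(outs))
    inlet_of_outlet = {}
    for inlet_label, idx in groups.items():
        sub = murray_split_fractions(areas[idx], config.murray_n)
        for j, i in enumerate(idx):
            frac[i] = sub[j]
            inlet_of_outlet[outs[i]] = inlet_label
    return dict(zip(outs, frac)), inlet_of_outlet


def solve_unsteady(network: VesselNetwork, inflows: dict,
                   fluid: FluidProperties | None = None,
                   config: SolverConfig | None = None) -> SimulationResult:
    """Run the pulsatile 0D solve and return the final cycle.

    ``inflows`` maps each inlet label to its :class:`FlowWaveform` (l/s);
    all waveforms must share one period.  Time is discretized at
    ``config.dt`` over ``config.cycles`` cycles starting from zero sac
    pressure; only the last cycle is returned.
    """
    fluid = fluid or FluidProperties()
    config = config or SolverConfig()
    network.validate()

    inlets = network.inlets
    labels = {n: network.graph.nodes[n].get("label", n) for n in inlets}
    missing = [labels[n] for n in inlets if labels[n] not in inflows]
    if missing:
        raise InvalidArgumentError(f"missing inflow waveform(s) for {missing}")
    periods = {inflows[labels[n]].period for n in inlets}
    if len({round(p, 12) for p in periods}) != 1:
        raise InvalidArgumentError("all inlet waveforms must share one period")
    period = float(next(iter(periods)))

    nodes = sorted(network.graph.nodes)
    n_idx = {n: i for i, n in enumerate(nodes)}
    V = len(nodes)
    edges = sorted(network.graph.edges(keys=True, data=True), key=lambda e: e[2])

    # orientation: inlet edges point inward, outlet edges outward, the rest
    # follow sorted node order
    oriented = []
    for u, v, k, d in edges:
        if network.node_kind(v) == "inlet" or network.node_kind(u) == "outlet" \
                or network.node_kind(u) == "aneurysm_sac":
            u, v = v, u
        elif network.node_kind(u) not in ("inlet", "aneurysm_sac") and \
                network.node_kind(v) not in ("outlet", "aneurysm_sac") and u > v:
            u, v = v, u
        oriented.append((u, v, k, d))

    sacs = network.sacs
    sac_idx = {s: i for i, s in enumerate(sacs)}
    g_of_edge = {}
    rows, cols, vals = [], [], []
    for u, v, k, d in oriented:
        g = 1.0 / edge_resistance(d["radius"] * MM, d["length"] * MM, fluid)
        g_of_edge[k] = g
        iu, iv = n_idx[u], n_idx[v]
        rows += [iu, iv, iu, iv]
        cols += [iu, iv, iv, iu]
        vals += [g, g, -g, -g]
    L = sparse.coo_matrix((vals, (rows, cols)), shape=(V, V)).tocsc()

    # sac capacitance (implicit Euler): C/dt on the sac diagonal
    C_over_dt = np.zeros(V)
    for s in sacs:
        C = network.graph.nodes[s]["sac_compliance_m3_per_pa"]
        C_over_dt[n_idx[s]] = C / config.dt
    A = (L + sparse.diags(C_over_dt)).tolil()

    ref = config.reference_node
    if ref is None:
        ref = network.outlets[0] if network.outlets else nodes[0]
    iref = n_idx[ref]
    A[iref, :] = 0.0
    A[iref, iref] = 1.0
    A = A.tocsc()
    try:
        lu = splu(A)
    except RuntimeError as exc:  # pragma: no cover
        raise InvalidArgumentError(f"singular nodal system: {exc}") from exc

    fractions, inlet_of_outlet = _outlet_fraction_map(network, config)
    outs = network.outlets

    n_per = int(round(period / config.dt))
    if abs(n_per * config.dt - period) > 1e-9:
        warnings.warn("period is not an integer multiple of dt; the cycle "
                      "grid is rounded", stacklevel=2)
    n_total = n_per * config.cycles
    E = len(oriented)
    Q_out = np.zeros((E, n_per))
    P_out = np.zeros((V, n_per))
    sacP_out = {s: np.zeros(n_per) for s in sacs}
    sacQ_out = {s: np.zeros(n_per) for s in sacs}

    p_sac_prev = np.zeros(len(sacs))
    inflow_at = {labels[n]: inflows[labels[n]] for n in inlets}
    max_residual = 0.0
    max_q = 0.0

    for step in range(n_total):
        t = (step + 1) * config.dt
        q_in = {lbl: float(wf.at(t)) * LPS for lbl, wf in inflow_at.items()}
        q_tot = sum(q_in.values())
        b = np.zeros(V)
        for n in inlets:
            b[n_idx[n]] += q_in[labels[n]]
        for o in outs:
            if inlet_of_outlet is None:
                b[n_idx[o]] -= fractions[o] * q_tot
            else:
                b[n_idx[o]] -= fractions[o] * q_in[inlet_of_outlet[o]]
        for s in sacs:
            b[n_idx[s]] += C_over_dt[n_idx[s]] * p_sac_prev[sac_idx[s]]
        b_solve = b.copy()
        b_solve[iref] = 0.0
        p = lu.solve(b_solve)
        for s in sacs:
            p_sac_prev[sac_idx[s]] = p[n_idx[s]]

        if step >= n_total - n_per:
            j = step - (n_total - n_per)
            P_out[:, j] = p
            for e, (u, v, k, d) in enumerate(oriented):
                Q_out[e, j] = g_of_edge[k] * (p[n_idx[u]] - p[n_idx[v]])
            # conservation residual at interior nodes
            res = A @ p - b
            res[iref] = 0.0
            interior = [i for n, i in n_idx.items()
                        if network.node_kind(n) in ("junction", "internal")]
            if interior:
                max_residual = max(max_residual, float(np.abs(res[interior]).max()))
            max_q = max(max_q, float(np.abs(Q_out[:, j]).max()), abs(q_tot))
            for s in sacs:
                sacP_out[s][j] = p[n_idx[s]]
    # neck flow: the oriented edge into each sac
    for s in sacs:
        for e, (u, v, k, d) in enumerate(oriented):
            if d["kind"] == "neck" and v == s:
                sacQ_out[s] = Q_out[e].copy()

    times = (np.arange(n_per) + 1) * config.dt
    tau = np.zeros_like(Q_out)
    for e, (u, v, k, d) in enumerate(oriented):
        tau[e] = poiseuille_wall_shear(Q_out[e], d["radius"] * MM, fluid)

    return SimulationResult(
        times=times, period=period, dt=config.dt,
        edge_ids=[k for _, _, k, _ in oriented],
        edge_orientation={k: (u, v) for u, v, k, _ in oriented},
        edge_radius_m={k: d["radius"] * MM for _, _, k, d in oriented},
        Q=Q_out, tau=tau, node_ids=nodes, P=P_out,
        sac_pressure=sacP_out, sac_neck_flow=sacQ_out,
        conservation_residual=max_residual / max(max_q, 1e-30) if max_q else 0.0)


# ---------------------------------------------------------------------------
# Womersley profile reconstruction
# ---------------------------------------------------------------------------

@dataclass
class PlaneSample:
    """Analytic radial velocity samples on a cross-sectional plane."""

    plane_id: str
    radius_m: float
    radii: np.ndarray           # (n_radial,) sample radii in m
    weights: np.ndarray         # quadrature weights for int v * 2 pi r dr
    V: np.ndarray               # (n_radial, T) axial velocity m/s
    Q: np.ndarray               # (T,) m^3/s
    times: np.ndarray
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    @property
    def area(self) -> float:
        return float(np.pi * self.radius_m ** 2)

    def integrated_flow(self) -> np.ndarray:
        """Radial quadrature of the profile: should reproduce Q(t)."""
        return self.weights @ self.V


def womersley_profile(flow_series: np.ndarray, radius: float,
                      fluid: FluidProperties | None = None,
                      n_harmonics: int = 8, n_radial: int = 32,
                      period: float | None = None,
                      plane_id: str = "plane") -> PlaneSample:
    """Reconstruct the pulsatile laminar pipe-flow profile from a periodic
    flow series Q(t) (m^3/s, uniform grid over one period).

    The steady Fourier component maps to the parabolic Poiseuille profile;
    harmonic k maps to the annular-Bessel Womersley solution at Womersley
    number alpha_k = r sqrt(k omega rho / mu).  Radial quadrature of the
    returned samples reproduces Q(t).
    """
    fluid = fluid or FluidProperties()
    q = np.asarray(flow_series, dtype=float)
    if q.ndim != 1 or q.size < 4:
        raise InvalidArgumentError("flow series must be 1D with >= 4 samples")
    if radius <= 0:
        raise InvalidArgumentError("radius must be > 0")
    if n_harmonics < 0:
        raise InvalidArgumentError("n_harmonics must be >= 0")
    N = q.size
    T = period if period is not None else 1.0
    omega = 2.0 * np.pi / T
    qh = np.fft.rfft(q) / N
    nyq = len(qh) - 1
    if n_harmonics > nyq:
        warnings.warn(f"n_harmonics truncated to the Nyquist limit {nyq}",
                      stacklevel=2)
        n_harmonics = nyq

    # Gauss-Legendre nodes in r on [0, R]; weights include the 2 pi r factor
    x, w = np.polynomial.legendre.leggauss(n_radial)
    r = 0.5 * radius * (x + 1.0)
    wr = 0.5 * radius * w * 2.0 * np.pi * r

    times = np.arange(N) / N * T
    Vrt = np.zeros((n_radial, N))
    area = np.pi * radius ** 2
    # steady component: parabolic
    Vrt += (2.0 * qh[0].real / area * (1.0 - (r / radius) ** 2))[:, None]
    for k in range(1, n_harmonics + 1):
        alpha = radius * np.sqrt(k * omega * fluid.rho / fluid.mu)
        beta = alpha * np.exp(1j * 3.0 * np.pi / 4.0)  # i^{3/2} alpha
        j0b = jv(0, beta)
        denom = 1.0 - 2.0 * jv(1, beta) / (beta * j0b)
        prof = (1.0 - jv(0, beta * r / radius) / j0b) / denom / area
        phase = np.exp(1j * k * omega * times)
        scale = 2.0 if k < nyq or N % 2 == 1 else 1.0
        Vrt += scale * np.real(qh[k] * prof[:, None] * phase[None, :])

    q_recon = np.zeros(N)
    q_recon += qh[0].real
    for k in range(1, n_harmonics + 1):
        scale = 2.0 if k < nyq or N % 2 == 1 else 1.0
        q_recon += scale * np.real(qh[k] * np.exp(1j * k * omega * times))

    return PlaneSample(plane_id=plane_id, radius_m=radius, radii=r, weights=wr,
                       V=Vrt, Q=q_recon, times=times)
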