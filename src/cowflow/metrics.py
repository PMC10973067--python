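"""Hemodynamic evaluation: normalized velocity profiles, TAWSS, OSI, neck
inflow rate (NIR), centerline velocity curves, spatial-mean normalization,
and the paired complex-vs-trimmed comparison report (deltas are always
complex minus trimmed)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hemodynamics import PlaneSample, SimulationResult
from .network import CenterlinePath, offtake_arcs
from .types import InvalidArgumentError, VesselNetwork

M3S_TO_MLS = 1e6


def _period_average(y: np.ndarray, x: np.ndarray | None = None) -> float:
    """Trapezoidal time average over one period.

    A closed grid (first and last samples at the same phase) is integrated
    directly; an open periodic grid is averaged with wrap-around, which for
    uniform sampling is the plain mean.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise InvalidArgumentError("empty series")
    if x is not None:
        x = np.asarray(x, dtype=float)
        return float(np.trapezoid(y, x) / (x[-1] - x[0]))
    return float(np.mean(y))


def v_norm(plane: PlaneSample, time_index: int | None = None) -> np.ndarray:
    """Dimensionless velocity profile V * A_plane / Q_plane.

    The area-weighted mean of the output is 1 at every time by
    construction.  Times at which Q_plane = 0 are undefined and raise.
    """
    V = plane.V if time_index is None else plane.V[:, [time_index]]
    Q = plane.Q if time_index is None else plane.Q[[time_index]]
    if np.any(np.abs(Q) < 1e-300):
        raise InvalidArgumentError(
            "V_Norm is undefined on a plane with zero volumetric flow")
    out = V * plane.area / Q[None, :]
    return out if time_index is None else out[:, 0]


def tawss(tau: np.ndarray, times: np.ndarray | None = None) -> float:
    """Time-averaged magnitude of wall shear stress (Pa) over one period."""
    tau = np.asarray(tau, dtype=float)
    if tau.size == 0:
        raise InvalidArgumentError("empty shear series")
    return _period_average(np.abs(tau), times)


def osi(tau: np.ndarray, times: np.ndarray | None = None) -> float:
    """Oscillatory shear index 0.5 (1 - |int tau| / int |tau|), in [0, 0.5];
    0 for shear that never reverses, 0.5 for zero-mean oscillation."""
    tau = np.asarray(tau, dtype=float)
    if tau.size == 0:
        raise InvalidArgumentError("empty shear series")
    denom = _period_average(np.abs(tau), times)
    if denom == 0.0:
        warnings.warn("identically zero shear series; OSI defined as 0",
                      stacklevel=2)
        return 0.0
    value = 0.5 * (1.0 - abs(_period_average(tau, times)) / denom)
    return float(np.clip(value, 0.0, 0.5))


def nir(neck_flow: np.ndarray, times: np.ndarray | None = None
        ) -> tuple[np.ndarray, float]:
    """Neck inflow rate: the positive (into-sac) part of the neck flow,
    converted to ml/s, and its time average."""
    q = np.asarray(neck_flow, dtype=float)
    series = np.maximum(q, 0.0) * M3S_TO_MLS
    return series, _period_average(series, times)


def normalize_by_spatial_mean(values: np.ndarray) -> np.ndarray:
    """Divide a field by its spatial mean; the output mean is exactly 1."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InvalidArgumentError("empty region")
    mean = values.mean()
    if mean == 0.0:
        raise InvalidArgumentError("cannot normalize by a zero spatial mean")
    return values / mean


def centerline_velocity(result: SimulationResult, network: VesselNetwork,
                        path: CenterlinePath, n_points: int = 50, *,
                        radius_profile: CenterlinePath | None = None
                        ) -> pd.DataFrame:
    """Time-averaged cross-section mean velocity Q_bar / (pi r^2) at
    ``n_points`` equidistant arc-length stations along an inlet-rooted
    centerline.  ``radius_profile`` substitutes another path's radii by
    arc length (used to evaluate paired models on the shared lumen
    geometry)."""
    if network.node_kind(path.node_ids[0]) != "inlet":
        raise InvalidArgumentError("centerline path must start at an inlet")
    rprof = radius_profile if radius_profile is not None else path
    stations = np.linspace(0.0, path.length, n_points + 2)[1:-1]
    rows = []
    for s in stations:
        eid = path.edge_at(s)
        q_mean = float(np.mean(np.abs(result.edge_flow(eid))))
        r_m = rprof.radius_at(s) * 1e-3
        rows.append({"s_mm": float(s), "edge_id": eid,
                     "v_m_s": q_mean / (np.pi * r_m ** 2)})
    return pd.DataFrame(rows)


def removed_offtake_arcs(network_complex: VesselNetwork,
                         network_trimmed: VesselNetwork,
                         path_complex: CenterlinePath,
                         path_trimmed: CenterlinePath,
                         tol: float = 1e-3) -> np.ndarray:
    """Arc positions where the complex model has an offtake junction but
    the trimmed model no longer does (the trimmed-away side branches)."""
    a_c = offtake_arcs(network_complex, path_complex)
    a_t = offtake_arcs(network_trimmed, path_trimmed)
    if a_c.size == 0:
        return a_c
    if a_t.size == 0:
        return a_c
    keep = [s for s in a_c if np.min(np.abs(a_t - s)) > tol]
    return np.asarray(keep)


@dataclass
class HemodynamicMetrics:
    """Per-edge, per-sac and per-path metrics of a single simulation."""

    case_id: str
    edge_table: pd.DataFrame                  # edge_id, tawss_Pa, osi
    sacs: dict = field(default_factory=dict)  # sac label -> metric dict
    centerlines: dict = field(default_factory=dict)  # path name -> DataFrame
    planes: dict = field(default_factory=dict)       # plane id -> metric dict


def compute_metrics(result: SimulationResult, network: VesselNetwork, *,
                    case_id: str = "case",
                    paths: dict | None = None,
                    shared_radii: dict | None = None,
                    n_points: int = 50,
                    planes: dict | None = None) -> HemodynamicMetrics:
    """Evaluate TAWSS/OSI per edge, NIR and shear surrogates per aneurysm
    sac, centerline velocity curves for the given paths, and V_Norm
    summaries for the given Womersley planes.

    The sac wall-shear surrogate is the Poiseuille shear of the neck edge
    (reported as ``wss_proxy``); in a 0D sac its spatial mean and maximum
    coincide.
    """
    rows = [{"edge_id": eid, "tawss_Pa": tawss(result.tau[i]),
             "osi": osi(result.tau[i])} for i, eid in enumerate(result.edge_ids)]
    m = HemodynamicMetrics(case_id=case_id, edge_table=pd.DataFrame(rows))

    for sac_id, q_neck in result.sac_neck_flow.items():
        label = network.graph.nodes[sac_id].get("label", sac_id)
        neck_eid = next(k for k, (u, v) in result.edge_orientation.items()
                        if v == sac_id)
        tau_neck = result.edge_tau(neck_eid)
        series, mean = nir(q_neck)
        m.sacs[label] = {
            "nir_ml_s": series, "nir_mean_ml_s": mean,
            "wss_proxy_Pa": np.abs(tau_neck),
            "mean_wss_Pa": float(np.mean(np.abs(tau_neck))),
            "max_wss_Pa": float(np.max(np.abs(tau_neck))),
            "tawss_Pa": tawss(tau_neck), "osi": osi(tau_neck),
        }

    for name, path in (paths or {}).items():
        rprof = (shared_radii or {}).get(name)
        m.centerlines[name] = centerline_velocity(result, network, path,
                                                  n_points, radius_profile=rprof)

    for pid, plane in (planes or {}).items():
        vn = v_norm(plane)
        wmean = plane.weights @ vn / plane.area
        m.planes[pid] = {
            "v_norm_mean_abs_dev": float(np.max(np.abs(wmean - 1.0))),
            "centerline_v_norm_peak": float(np.max(vn[0])),
            "time_avg_mean_velocity_m_s": float(np.mean(plane.Q) / plane.area),
        }
    return m


@dataclass
class ComparisonReport:
    """Paired complex-vs-trimmed deltas; every delta is complex - trimmed."""

    case_complex: str
    case_trimmed: str
    sac_deltas: dict = field(default_factory=dict)
    centerline: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    sign_convention: str = "complex_minus_trimmed"

    def to_dict(self) -> dict:
        cl = {}
        for name, d in self.centerline.items():
            cl[name] = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                        for k, v in d.items()}
        return {"sign_convention": self.sign_convention,
                "case_complex": self.case_complex,
                "case_trimmed": self.case_trimmed,
                "sac_deltas": self.sac_deltas, "centerline": cl,
                "summary": self.summary}


def compare_models(metrics_complex: HemodynamicMetrics,
                   metrics_trimmed: HemodynamicMetrics,
                   removed_offtakes: dict | None = None) -> ComparisonReport:
    """Pair the two metric sets by label and emit delta metrics.

    ``removed_offtakes`` optionally maps path names to arc positions (mm)
    of offtakes present only in the complex model; stations distal to the
    first removed offtake are then classified and the fraction at which
    the trimmed model overestimates velocity is reported.
    """
    mc, mt = metrics_complex, metrics_trimmed
    mismatched = sorted(set(mc.sacs) ^ set(mt.sacs)) + \
        sorted(set(mc.centerlines) ^ set(mt.centerlines))
    if mismatched:
        raise InvalidArgumentError(f"unpaired labels between models: {mismatched}")

    rep = ComparisonReport(case_complex=mc.case_id, case_trimmed=mt.case_id)
    for label in sorted(mc.sacs):
        a, b = mc.sacs[label], mt.sacs[label]
        rep.sac_deltas[label] = {
            "delta_nir_mean_ml_s": a["nir_mean_ml_s"] - b["nir_mean_ml_s"],
            "delta_mean_wss_Pa": a["mean_wss_Pa"] - b["mean_wss_Pa"],
            "delta_max_wss_Pa": a["max_wss_Pa"] - b["max_wss_Pa"],
            "delta_tawss_Pa": a["tawss_Pa"] - b["tawss_Pa"],
            "delta_osi": a["osi"] - b["osi"],
        }

    max_abs_dv = 0.0
    for name in sorted(mc.centerlines):
        ca, cb = mc.centerlines[name], mt.centerlines[name]
        if len(ca) != len(cb) or not np.allclose(ca["s_mm"], cb["s_mm"]):
            raise InvalidArgumentError(
                f"centerline {name!r} sampled on different stations")
        dv = ca["v_m_s"].to_numpy() - cb["v_m_s"].to_numpy()
        entry = {"s_mm": ca["s_mm"].to_numpy(), "delta_v_m_s": dv,
                 "max_abs_delta_v_m_s": float(np.max(np.abs(dv)))}
        max_abs_dv = max(max_abs_dv, entry["max_abs_delta_v_m_s"])
        if removed_offtakes and name in removed_offtakes and \
                len(removed_offtakes[name]) > 0:
            s0 = float(np.min(removed_offtakes[name]))
            distal = ca["s_mm"].to_numpy() > s0
            entry["first_removed_offtake_s_mm"] = s0
            entry["n_distal_stations"] = int(distal.sum())
            if distal.any():
                entry["distal_overestimation_fraction"] = \
                    float(np.mean(dv[distal] < 0.0))
        rep.centerline[name] = entry

    mean_tawss = lambda m: float(m.edge_table["tawss_Pa"].mean())  # noqa: E731
    rep.summary = {
        "delta_spatial_mean_tawss_Pa": mean_tawss(mc) - mean_tawss(mt),
        "max_abs_delta_centerline_v_m_s": max_abs_dv,
        "delta_nir_mean_ml_s": {lbl: d["delta_nir_mean_ml_s"]
                                for lbl, d in rep.sac_deltas.items()},
    }
    return rep
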