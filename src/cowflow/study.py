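"""Four-case study workflow: {complex, trimmed} x {physiological,
pathological} on one synthetic circle-of-Willis phantom, with paired
comparison reports.

The complex model carries every template outlet; the trimmed model keeps
only the N most prominent outlet cross sections.  The pathological
versions add two diameter-matched saccular aneurysms, one on the right and
one on the left middle cerebral artery, to both models.  All stages are
deterministic under a fixed seed and every artifact is hashed into a
manifest, so a rerun with the same configuration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as cio
from .hemodynamics import (FluidProperties, SimulationResult, SolverConfig,
                           solve_unsteady, womersley_profile)
from .metrics import (HemodynamicMetrics, compare_models, compute_metrics,
                      removed_offtake_arcs)
from .network import (extract_path, find_edge_near, outlet_prominence,
                      skeletonize_and_build, trim_network, attach_aneurysm,
                      _outlet_inlet_branch, branch_summary)
from .phantom import (default_inlet_waveforms, generate_cow_template,
                      make_aneurysm_spec, rasterize_network)
from .segmentation import dice_coefficient, seeds_from_openings, segment_volume
from .types import CowflowError, VesselNetwork

log = logging.getLogger("cowflow.study")


@dataclass
class AneurysmConfig:
    branch: str = "M1r"          # template branch the sac sits on
    label: str = "IA-A"
    arc_position: float = 0.5
    sac_volume_mm3: float = 100.0
    compliance_m3_per_pa: float = 1e-12
    neck_ratio: float = 1.0
    neck_length_mm: float = 1.0


@dataclass
class StudyConfig:
    """Resolved configuration of one four-case run (serialized beside the
    outputs)."""

    seed: int = 0
    n_outlets_complex: int = 60
    keep_outlets: int = 10
    template_scale: float = 0.8
    min_radius_mm: float = 0.85        # resolvability floor at 0.32 mm voxels
    leaf_radius_lo_mm: float = 0.85    # distal outlet radii are drawn in
    leaf_radius_hi_mm: float = 1.25    # this range (above the floor)
    skip_imaging: bool = False
    spacing_mm: float = 0.32
    lumen_intensity: float = 100.0
    background_intensity: float = 0.0
    noise_sd: float = 5.0
    period_s: float = 1.0
    pulsatility: float = 0.5
    waveform_samples: int = 200
    dt_s: float = 0.001
    cycles: int = 3
    murray_n: float = 2.0
    mu_pa_s: float = 0.004
    rho_kg_m3: float = 1055.0
    aneurysms: tuple = (AneurysmConfig("M1r", "IA-A"), AneurysmConfig("M1l", "IA-B"))
    centerline_points: int = 50
    write_volumes: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["aneurysms"] = [dataclasses.asdict(a) for a in self.aneurysms]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        d["aneurysms"] = tuple(AneurysmConfig(**a) for a in d.get("aneurysms", []))
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _result_frame(result: SimulationResult) -> pd.DataFrame:
    rows = []
    for i, eid in enumerate(result.edge_ids):
        for j, t in enumerate(result.times):
            rows.append((round(float(t), 9), eid, result.Q[i, j], result.tau[i, j]))
    return pd.DataFrame(rows, columns=["time_s", "edge_id", "Q_m3s", "tau_Pa"])


def _metrics_frame(m: HemodynamicMetrics) -> pd.DataFrame:
    rows = [{"entity_id": r.edge_id, "metric": "tawss", "value": r.tawss_Pa,
             "units": "Pa"} for r in m.edge_table.itertuples()]
    rows += [{"entity_id": r.edge_id, "metric": "osi", "value": r.osi,
              "units": "1"} for r in m.edge_table.itertuples()]
    for label, d in m.sacs.items():
        for key, units in (("nir_mean_ml_s", "ml/s"), ("mean_wss_Pa", "Pa"),
                           ("max_wss_Pa", "Pa"), ("tawss_Pa", "Pa"), ("osi", "1")):
            rows.append({"entity_id": label, "metric": key, "value": d[key],
                         "units": units})
    return pd.DataFrame(rows)


def run_study(config: StudyConfig, out_dir) -> Path:
    """Execute phantom -> (segmentation) -> network -> four simulations ->
    metrics -> paired comparisons; returns the artifact directory."""
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_times: dict[str, float] = {}
    artifacts: list[Path] = []

    def _stage(name):
        stage_times[name] = time.time() - t0
        log.info("stage %s done at %.1f s", name, stage_times[name])

    def _write(path: Path):
        artifacts.append(path)
        return path

    (out / "config.json").write_text(
        json.dumps(config.to_dict(), indent=1, sort_keys=True))
    _write(out / "config.json")

    # --- phantom -------------------------------------------------------------
    template = generate_cow_template(
        config.n_outlets_complex, config.seed, scale=config.template_scale,
        min_radius=config.min_radius_mm,
        leaf_radius_range=(config.leaf_radius_lo_mm, config.leaf_radius_hi_mm))
    _stage("phantom")

    # --- imaging chain (optional) -------------------------------------------
    segmentation_report = {}
    if config.skip_imaging:
        net_complex = template
    else:
        try:
            volume, gt = rasterize_network(
                template, spacing=config.spacing_mm,
                lumen_intensity=config.lumen_intensity,
                background_intensity=config.background_intensity,
                noise_sd=config.noise_sd, seed=config.seed + 1)
        except CowflowError as exc:
            raise CowflowError(f"stage rasterize failed: {exc}") from exc
        seeds = seeds_from_openings(gt.openings, volume)
        mask = segment_volume(volume, seeds)
        segmentation_report["dice_vs_ground_truth"] = dice_coefficient(
            mask.mask, gt.mask)
        net_complex = skeletonize_and_build(mask, gt.openings, strict=False)
        segmentation_report["n_outlets_recovered"] = len(net_complex.outlets)
        net_complex.metadata["branch_to_inlet"] = \
            template.metadata.get("branch_to_inlet", {})
        if config.write_volumes:
            _write(cio.save_volume(volume, out / "volume.nii"))
            _write(cio.save_mask(mask.mask, mask.spacing, mask.origin,
                                 out / "lumen_mask.nii"))
        _stage("segmentation")

    # --- geometries ----------------------------------------------------------
    net_trimmed = trim_network(net_complex, config.keep_outlets)
    kept_outlets = net_trimmed.outlets

    def _attach_all(net: VesselNetwork) -> VesselNetwork:
        for ia in config.aneurysms:
            tmpl_edges = template.edges_with_branch(ia.branch)
            if not tmpl_edges:
                raise CowflowError(f"stage aneurysm failed: no branch {ia.branch!r}")
            u, v, d = template.edge_by_id(tmpl_edges[0])
            midpoint = 0.5 * (template.position(u) + template.position(v))
            edge_id = find_edge_near(net, midpoint)
            spec = make_aneurysm_spec(
                net, edge_id, arc_position=ia.arc_position,
                sac_volume=ia.sac_volume_mm3, compliance=ia.compliance_m3_per_pa,
                neck_ratio=ia.neck_ratio, neck_length=ia.neck_length_mm,
                label=ia.label)
            net = attach_aneurysm(net, spec)
        return net

    cases: dict[str, VesselNetwork] = {
        "complex_physiological": net_complex,
        "trimmed_physiological": net_trimmed,
        "complex_pathological": _attach_all(net_complex),
    }
    cases["trimmed_pathological"] = trim_network(
        cases["complex_pathological"], kept_outlets)
    for name, net in cases.items():
        _write(cio.save_network(net, out / f"network_{name}.json"))
    _write((out / "branch_summary.csv"))
    pd.merge(branch_summary(net_complex), branch_summary(net_trimmed),
             on="inlet_branch", how="outer", suffixes=("_complex", "_trimmed")) \
        .to_csv(out / "branch_summary.csv", index=False, float_format="%.9g")
    _stage("networks")

    # --- boundary conditions -------------------------------------------------
    waveforms = default_inlet_waveforms(config.period_s, config.pulsatility,
                                        config.waveform_samples)
    for label, wf in waveforms.items():
        _write(cio.save_waveform(wf, out / f"inflow_{label}.csv"))
    fluid = FluidProperties(mu=config.mu_pa_s, rho=config.rho_kg_m3)
    solver = SolverConfig(dt=config.dt_s, cycles=config.cycles,
                          murray_n=config.murray_n)

    # --- simulations ---------------------------------------------------------
    results: dict[str, SimulationResult] = {}
    for name, net in cases.items():
        results[name] = solve_unsteady(net, waveforms, fluid, solver)
        df = _result_frame(results[name])
        df.to_csv(out / f"result_{name}.csv", index=False, float_format="%.9g")
        _write(out / f"result_{name}.csv")
    _stage("simulations")

    # --- paths shared between paired models ---------------------------------
    def _paths_for(net: VesselNetwork) -> dict:
        """inlet -> most prominent kept outlet of that inlet's territory."""
        chosen = {}
        prom = dict(outlet_prominence(net_trimmed))
        for o in kept_outlets:
            inlet = _outlet_inlet_branch(net_trimmed, o)
            if inlet and (inlet not in chosen or prom[o] > prom[chosen[inlet]]):
                chosen[inlet] = o
        return {f"{inlet}->{o}": extract_path(net, inlet, o)
                for inlet, o in sorted(chosen.items())}

    paths = {name: _paths_for(net) for name, net in cases.items()}
    shared = {pname: p for pname, p in paths["complex_physiological"].items()}
    shared_path = {pname: p for pname, p in paths["complex_pathological"].items()}

    # --- metrics -------------------------------------------------------------
    def _planes(name):
        res, pths = results[name], paths[name]
        out_planes = {}
        for pname, p in sorted(pths.items()):
            eid = p.seg_edge_ids[0]
            out_planes[pname] = womersley_profile(
                res.edge_flow(eid), res.edge_radius_m[eid], fluid,
                period=res.period, plane_id=pname)
        return out_planes

    metrics = {}
    for name in cases:
        sh = shared if name.endswith("physiological") else shared_path
        metrics[name] = compute_metrics(
            results[name], cases[name], case_id=name, paths=paths[name],
            shared_radii=sh, n_points=config.centerline_points,
            planes=_planes(name))
        _metrics_frame(metrics[name]).to_csv(
            out / f"metrics_{name}.csv", index=False, float_format="%.9g")
        _write(out / f"metrics_{name}.csv")
    _stage("metrics")

    # --- comparisons ---------------------------------------------------------
    reports = {}
    for pairing, (cname, tname) in {
            "physiological": ("complex_physiological", "trimmed_physiological"),
            "pathological": ("complex_pathological", "trimmed_pathological")}.items():
        removed = {}
        for pname in paths[cname]:
            removed[pname] = removed_offtake_arcs(
                cases[cname], cases[tname],
                paths[cname][pname], paths[tname][pname]).tolist()
        rep = compare_models(metrics[cname], metrics[tname],
                             removed_offtakes=removed)
        payload = rep.to_dict()
        payload["removed_offtakes_mm"] = removed
        if pairing == "physiological" and segmentation_report:
            payload["segmentation"] = segmentation_report
        (out / f"comparison_{pairing}.json").write_text(
            json.dumps(payload, indent=1, sort_keys=True, default=float))
        _write(out / f"comparison_{pairing}.json")
        reports[pairing] = rep
    _stage("comparisons")

    manifest = {
        "artifacts": {p.name: _sha256(p) for p in sorted(set(artifacts))},
        "seed": config.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (out / "run.log").write_text(json.dumps(
        {"stage_seconds": stage_times, "total_seconds": time.time() - t0},
        indent=1, sort_keys=True))
    return out
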