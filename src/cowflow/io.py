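"""Standard-format I/O: NIfTI volumes and masks, a documented JSON schema
for vessel networks (with optional GraphML export), 2-column CSV waveforms
and JSON aneurysm specs."""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import nibabel as nib
import numpy as np
import pandas as pd

from .types import (
    AneurysmSpec,
    FlowWaveform,
    ImageVolume,
    UnsupportedInputError,
    VesselNetwork,
)

NETWORK_SCHEMA_VERSION = "1.0"


# -- volumes ----------------------------------------------------------------

def save_volume(volume: ImageVolume, path) -> Path:
    """Write as NIfTI; the affine encodes isotropic spacing and the origin."""
    path = Path(path)
    affine = np.diag([volume.spacing] * 3 + [1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), affine)
    nib.save(img, path)
    return path


def load_volume(path) -> ImageVolume:
    img = nib.load(str(path))
    affine = img.affine
    steps = np.linalg.norm(affine[:3, :3], axis=0)
    if not np.allclose(steps, steps[0], rtol=1e-4):
        raise UnsupportedInputError(
            f"anisotropic spacing {steps} is not supported; resample to isotropic")
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    return ImageVolume(data=data, spacing=float(steps[0]), origin=affine[:3, 3].copy())


def save_mask(mask: np.ndarray, spacing: float, origin, path) -> Path:
    path = Path(path)
    affine = np.diag([spacing] * 3 + [1.0])
    affine[:3, 3] = np.asarray(origin, dtype=float)
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), path)
    return path


# -- networks ---------------------------------------------------------------

def network_to_dict(network: VesselNetwork) -> dict:
    nodes = []
    for n, d in sorted(network.graph.nodes(data=True)):
        entry = {"id": n, "position_mm": [float(x) for x in d["position"]],
                 "kind": d["kind"], "label": d.get("label", "")}
        for k in ("sac_volume_mm3", "sac_compliance_m3_per_pa"):
            if k in d:
                entry[k] = d[k]
        nodes.append(entry)
    edges = []
    for u, v, k, d in sorted(network.graph.edges(keys=True, data=True),
                             key=lambda e: e[2]):
        entry = {"id": k, "nodes": [u, v], "length_mm": d["length"],
                 "radius_mm": d["radius"], "kind": d["kind"]}
        if d.get("branch"):
            entry["branch"] = d["branch"]
        edges.append(entry)
    return {"schema": NETWORK_SCHEMA_VERSION, "units": "mm",
            "metadata": network.metadata, "nodes": nodes, "edges": edges}


def network_from_dict(payload: dict) -> VesselNetwork:
    net = VesselNetwork(metadata=dict(payload.get("metadata", {})))
    for n in payload["nodes"]:
        extra = {k: n[k] for k in ("sac_volume_mm3", "sac_compliance_m3_per_pa")
                 if k in n}
        net.add_node(n["id"], n["position_mm"], kind=n["kind"],
                     label=n.get("label", ""), **extra)
    for e in payload["edges"]:
        u, v = e["nodes"]
        net.add_edge(u, v, e["id"], radius=e["radius_mm"], length=e["length_mm"],
                     kind=e["kind"], branch=e.get("branch", ""))
    return net


def save_network(network: VesselNetwork, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(network_to_dict(network), indent=1, sort_keys=True))
    return path


def load_network(path) -> VesselNetwork:
    return network_from_dict(json.loads(Path(path).read_text()))


def export_graphml(network: VesselNetwork, path) -> Path:
    """GraphML export (positions flattened to scalar attributes)."""
    g = nx.MultiGraph()
    for n, d in network.graph.nodes(data=True):
        p = d["position"]
        g.add_node(n, x_mm=float(p[0]), y_mm=float(p[1]), z_mm=float(p[2]),
                   kind=d["kind"], label=d.get("label", ""))
    for u, v, k, d in network.graph.edges(keys=True, data=True):
        g.add_edge(u, v, key=k, radius_mm=d["radius"], length_mm=d["length"],
                   kind=d["kind"], branch=d.get("branch", ""))
    nx.write_graphml(g, str(path))
    return Path(path)


# -- waveforms and specs ----------------------------------------------------

def save_waveform(waveform: FlowWaveform, path) -> Path:
    df = pd.DataFrame({"time_s": waveform.times, "flow_l_per_s": waveform.values})
    df.to_csv(path, index=False, float_format="%.12g")
    return Path(path)


def load_waveform(path, label: str = "") -> FlowWaveform:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    return FlowWaveform(period=float(t[-1] - t[0]),
                        values=df["flow_l_per_s"].to_numpy(), label=label)


def save_aneurysm_spec(spec: AneurysmSpec, path) -> Path:
    payload = {"edge_id": spec.edge_id, "arc_position": spec.arc_position,
               "neck_radius_mm": spec.neck_radius, "sac_volume_mm3": spec.sac_volume,
               "compliance_m3_per_pa": spec.compliance,
               "neck_length_mm": spec.neck_length, "label": spec.label}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
    return Path(path)


def load_aneurysm_spec(path) -> AneurysmSpec:
    p = json.loads(Path(path).read_text())
    return AneurysmSpec(edge_id=p["edge_id"], arc_position=p["arc_position"],
                        neck_radius=p["neck_radius_mm"], sac_volume=p["sac_volume_mm3"],
                        compliance=p["compliance_m3_per_pa"],
                        neck_length=p["neck_length_mm"], label=p.get("label", "IA"))
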