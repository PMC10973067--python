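"""Core containers shared across the pipeline.

Geometry is held in millimetres throughout the imaging and network stages;
the hemodynamic solver converts to SI internally.  A :class:`VesselNetwork`
wraps a :class:`networkx.MultiGraph` (multi-edges are needed so that two
parallel limbs between the same pair of junctions — a communicating-artery
loop in its most degenerate form — remain distinct edges).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

NODE_KINDS = {"inlet", "outlet", "junction", "internal", "aneurysm_sac"}
EDGE_KINDS = {"vessel", "neck"}
INLET_LABELS = ("ICAl", "ICAr", "BA")


class CowflowError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(CowflowError, ValueError):
    pass


class ResourceLimitError(CowflowError, RuntimeError):
    pass


class UnsupportedInputError(CowflowError, ValueError):
    pass


@dataclass
class VesselNetwork:
    """Vessel graph: nodes carry a position (mm), a kind and a label;
    edges carry length (mm), radius (mm) and a kind (vessel or neck)."""

    graph: nx.MultiGraph = field(default_factory=nx.MultiGraph)
    metadata: dict = field(default_factory=dict)

    # -- construction helpers -------------------------------------------------
    def add_node(self, node_id: str, position, kind: str = "junction",
                 label: str = "", **attrs) -> str:
        if kind not in NODE_KINDS:
            raise InvalidArgumentError(f"unknown node kind {kind!r}")
        pos = np.asarray(position, dtype=float)
        if pos.shape != (3,):
            raise InvalidArgumentError("position must be a 3-vector (mm)")
        self.graph.add_node(node_id, position=pos, kind=kind, label=label, **attrs)
        return node_id

    def add_edge(self, u: str, v: str, edge_id: str, radius: float,
                 length: float | None = None, kind: str = "vessel",
                 **attrs) -> str:
        if kind not in EDGE_KINDS:
            raise InvalidArgumentError(f"unknown edge kind {kind!r}")
        if radius <= 0:
            raise InvalidArgumentError("edge radius must be > 0")
        dist = float(np.linalg.norm(self.position(u) - self.position(v)))
        if length is None:
            length = dist
        if length <= 0:
            raise InvalidArgumentError("edge length must be > 0")
        if length < dist - 1e-9:
            raise InvalidArgumentError(
                f"edge length {length} shorter than endpoint distance {dist}")
        self.graph.add_edge(u, v, key=edge_id, radius=float(radius),
                            length=float(length), kind=kind, **attrs)
        return edge_id

    # -- queries --------------------------------------------------------------
    def position(self, node_id: str) -> np.ndarray:
        return self.graph.nodes[node_id]["position"]

    def node_kind(self, node_id: str) -> str:
        return self.graph.nodes[node_id]["kind"]

    def nodes_of_kind(self, kind: str) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == kind)

    @property
    def inlets(self) -> list[str]:
        return self.nodes_of_kind("inlet")

    @property
    def outlets(self) -> list[str]:
        return self.nodes_of_kind("outlet")

    @property
    def sacs(self) -> list[str]:
        return self.nodes_of_kind("aneurysm_sac")

    def edge_ids(self) -> list[str]:
        return sorted(k for _, _, k in self.graph.edges(keys=True))

    def edge_by_id(self, edge_id: str) -> tuple[str, str, dict]:
        for u, v, k, d in self.graph.edges(keys=True, data=True):
            if k == edge_id:
                return u, v, d
        raise InvalidArgumentError(f"no edge with id {edge_id!r}")

    def edges_with_branch(self, branch: str) -> list[str]:
        return sorted(k for _, _, k, d in self.graph.edges(keys=True, data=True)
                      if d.get("branch") == branch)

    def node_by_label(self, label: str) -> str:
        for n, d in self.graph.nodes(data=True):
            if d.get("label") == label:
                return n
        raise InvalidArgumentError(f"no node labelled {label!r}")

    def copy(self) -> "VesselNetwork":
        return VesselNetwork(graph=self.graph.copy(), metadata=dict(self.metadata))

    # -- validation -----------------------------------------------------------
    def validate(self, cow_template: bool = False) -> None:
        """Raise if the structural invariants do not hold."""
        g = self.graph
        if g.number_of_nodes() == 0:
            raise InvalidArgumentError("empty network")
        if not nx.is_connected(g):
            raise InvalidArgumentError("network graph is not connected")
        for n, d in g.nodes(data=True):
            if d["kind"] in ("inlet", "outlet") and g.degree(n) != 1:
                raise InvalidArgumentError(
                    f"{d['kind']} node {n!r} has degree {g.degree(n)} (must be 1)")
            if d["kind"] == "aneurysm_sac":
                inc = list(g.edges(n, keys=True, data=True))
                if len(inc) != 1 or inc[0][3]["kind"] != "neck":
                    raise InvalidArgumentError(
                        f"aneurysm sac {n!r} must connect through exactly one neck edge")
        for u, v, k, d in g.edges(keys=True, data=True):
            if d["radius"] <= 0 or d["length"] <= 0:
                raise InvalidArgumentError(f"edge {k!r} has non-positive radius/length")
            dist = float(np.linalg.norm(self.position(u) - self.position(v)))
            if d["length"] < dist - 1e-6:
                raise InvalidArgumentError(
                    f"edge {k!r} length {d['length']} < endpoint distance {dist}")
        if cow_template:
            labels = sorted(g.nodes[n].get("label", "") for n in self.inlets)
            if labels != sorted(INLET_LABELS):
                raise InvalidArgumentError(
                    f"CoW template must have inlets labelled {INLET_LABELS}, got {labels}")


@dataclass
class ImageVolume:
    """Isotropic 3D scalar volume.  ``spacing`` is the voxel edge in mm and
    ``origin`` the world position (mm) of the centre of voxel (0,0,0)."""

    data: np.ndarray
    spacing: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing <= 0:
            raise InvalidArgumentError("spacing must be > 0")
        if self.data.ndim != 3:
            raise InvalidArgumentError("volume must be 3D")
        if min(self.data.shape) < 16:
            raise InvalidArgumentError("volume must have >= 16 voxels per axis")
        if not np.all(np.isfinite(self.data)):
            raise InvalidArgumentError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_coordinates(self, index) -> np.ndarray:
        """World position (mm) of a (fractional) voxel index."""
        return self.origin + np.asarray(index, dtype=float) * self.spacing


@dataclass
class GroundTruth:
    """Noise-free lumen labelling that accompanies a synthetic volume."""

    mask: np.ndarray                      # bool, same grid as the volume
    centerlines: list                     # list of (edge_id, Nx3 polyline mm)
    radii: dict                           # edge_id -> true radius (mm)
    openings: list = field(default_factory=list)  # dicts: label, kind, position

    def validate_against(self, volume: ImageVolume) -> None:
        if self.mask.shape != volume.shape:
            raise InvalidArgumentError("ground-truth mask shape != volume shape")
        for _, poly in self.centerlines:
            idx = np.rint((poly - volume.origin) / volume.spacing).astype(int)
            inb = np.all((idx >= 0) & (idx < np.array(volume.shape)), axis=1)
            if not np.all(self.mask[tuple(idx[inb].T)]):
                raise InvalidArgumentError("centerline point outside lumen mask")


@dataclass
class FlowWaveform:
    """One cardiac period of volumetric flow (l/s), sampled uniformly on an
    inclusive grid t = 0 … period so that the first and last samples coincide."""

    period: float
    values: np.ndarray                    # l/s
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.period <= 0:
            raise InvalidArgumentError("period must be > 0")
        if self.values.size < 50:
            raise InvalidArgumentError("waveform needs >= 50 samples per period")
        if abs(self.values[0] - self.values[-1]) > 1e-9:
            raise InvalidArgumentError("waveform must be periodic (first == last sample)")

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.period, self.values.size)

    @property
    def mean(self) -> float:
        """Time-averaged flow (l/s), trapezoidal rule over the period."""
        return float(np.trapezoid(self.values, self.times) / self.period)

    def at(self, t) -> np.ndarray:
        """Periodic linear interpolation, in l/s."""
        tm = np.mod(t, self.period)
        return np.interp(tm, self.times, self.values)


@dataclass
class AneurysmSpec:
    """Parametric saccular aneurysm to be attached on a vessel edge."""

    edge_id: str
    arc_position: float                   # 0..1 along the edge
    neck_radius: float                    # mm
    sac_volume: float                     # mm^3
    compliance: float                     # m^3/Pa
    neck_length: float = 1.0              # mm
    label: str = "IA"

    def validate(self, network: VesselNetwork) -> None:
        u, v, d = network.edge_by_id(self.edge_id)
        if d["kind"] != "vessel":
            raise InvalidArgumentError("aneurysms attach to vessel edges only")
        if not (0.0 <= self.arc_position <= 1.0):
            raise InvalidArgumentError("arc_position must lie in [0, 1]")
        if not (0 < self.neck_radius <= d["radius"] + 1e-12):
            raise InvalidArgumentError(
                "neck radius must be positive and <= parent edge radius")
        if self.sac_volume <= 0:
            raise InvalidArgumentError("sac volume must be > 0")
        if self.compliance <= 0:
            raise InvalidArgumentError("sac compliance must be > 0")
        if self.neck_length <= 0:
            raise InvalidArgumentError("neck length must be > 0")
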