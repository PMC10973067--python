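"""Synthetic inputs: circle-of-Willis network templates, angiography-like
volumes with ground truth, inlet flow waveforms and aneurysm specifications.

The template is not any subject's anatomy.  It reproduces the *structure*
that matters for model-complexity experiments: three inlets (left/right
internal carotid and basilar artery), the communicating-artery loops, six
main trunks (MCA/ACA/PCA, left and right) and a configurable number of
distal outlets whose radii follow Murray's physiological branching rule
r_parent^3 = sum r_child^3.
"""

from __future__ import annotations

import numpy as np

from .types import (
    AneurysmSpec,
    FlowWaveform,
    GroundTruth,
    ImageVolume,
    InvalidArgumentError,
    ResourceLimitError,
    VesselNetwork,
)

#: Mean volumetric inflow per inlet in l/s (subject-derived reference values).
DEFAULT_INLET_MEAN_FLOWS = {"ICAr": 3.434e-3, "ICAl": 3.065e-3, "BA": 2.332e-3}

#: Inlet cross-sectional areas (mm^2) of the reference subject.
DEFAULT_INLET_AREAS = {"ICAr": 8.76, "ICAl": 2.07, "BA": 2.00}

# Trunk offtake sites: label, owning inlet, ring attachment, growth
# direction.  Directions are spread so the six distal trees occupy
# well-separated solid-angle sectors.
_TRUNKS = (
    ("MCAl", "ICAl", "aca_mca_l", (-0.92, 0.10, 0.25)),
    ("MCAr", "ICAr", "aca_mca_r", (0.92, 0.10, 0.25)),
    ("ACAl", "ICAl", "aca_root_l", (-0.45, 0.55, 0.70)),
    ("ACAr", "ICAr", "aca_root_r", (0.45, 0.55, 0.70)),
    ("PCAl", "BA", "pca_j_l", (-0.45, -0.82, 0.36)),
    ("PCAr", "BA", "pca_j_r", (0.45, -0.82, 0.36)),
)


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _perp_basis(d):
    d = _unit(d)
    ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = _unit(np.cross(d, ref))
    e2 = np.cross(d, e1)
    return e1, e2


def _rotate_about(v, axis, angle):
    axis = _unit(axis)
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c)


class _Builder:
    def __init__(self, net: VesselNetwork):
        self.net = net
        self._n = 0
        self._e = 0

    def node(self, position, kind="junction", label=""):
        nid = f"n{self._n:03d}"
        self._n += 1
        self.net.add_node(nid, position, kind=kind, label=label)
        return nid

    def edge(self, u, v, radius, branch="", kind="vessel", length=None):
        eid = f"e{self._e:03d}"
        self._e += 1
        self.net.add_edge(u, v, eid, radius=radius, length=length,
                          kind=kind, branch=branch)
        return eid


def generate_cow_template(n_outlets: int = 60, seed: int = 0, *,
                          scale: float = 1.0,
                          min_radius: float | None = None,
                          leaf_radius_range: tuple[float, float] = (0.55, 0.85),
                          ) -> VesselNetwork:
    """Build a circle-of-Willis-like network with 3 inlets and ``n_outlets``
    outlets.

    Parameters
    ----------
    n_outlets:
        Number of outlet nodes (>= 4).  60 emulates an exhaustively
        segmented model, 10 a conventionally trimmed one.
    seed:
        Controls leaf radii and the small geometric jitter; the same
        (n_outlets, seed) always yields the same network.
    scale:
        Multiplies all positions and lengths (not radii); shrinks or grows
        the phantom's physical extent.
    min_radius:
        Optional lower clamp (mm) applied to distal leaf radii before
        Murray aggregation — used to keep all vessels resolvable at a
        chosen voxel spacing.
    """
    if n_outlets < 4:
        raise InvalidArgumentError(
            "n_outlets must be >= 4 (cannot place one outlet per main trunk)")
    rng = np.random.default_rng(seed)
    net = VesselNetwork(metadata={
        "provenance": f"cowflow synthetic CoW template (n_outlets={n_outlets}, seed={seed})",
        "units": "mm",
        "inlet_mean_flows_l_per_s": dict(DEFAULT_INLET_MEAN_FLOWS),
        "reference_inlet_areas_mm2": dict(DEFAULT_INLET_AREAS),
    })
    b = _Builder(net)
    s = scale

    # --- core ring -----------------------------------------------------------
    pos = {
        "ica_term_l": np.array([-8.0, 0.0, 0.0]),
        "ica_term_r": np.array([8.0, 0.0, 0.0]),
        "bas_tip": np.array([0.0, -7.5, -0.5]),
        "pca_j_l": np.array([-4.8, -6.6, 0.4]),
        "pca_j_r": np.array([4.8, -6.6, 0.4]),
        "aca_mca_l": np.array([-10.5, 1.6, 1.8]),
        "aca_mca_r": np.array([10.5, 1.6, 1.8]),
        "aca_root_l": np.array([-2.2, 4.6, 1.4]),
        "aca_root_r": np.array([2.2, 4.6, 1.4]),
        "ica_in_l": np.array([-10.5, -3.0, -10.0]),
        "ica_in_r": np.array([10.5, -3.0, -10.0]),
        # slightly off-axis: exactly grid-aligned free-end branches erode
        # badly under 3D thinning
        "ba_in": np.array([0.5, -10.5, -10.0]),
    }
    nid = {k: b.node(p * s, kind="junction", label=k) for k, p in pos.items()}
    for k, lbl in (("ica_in_l", "ICAl"), ("ica_in_r", "ICAr"), ("ba_in", "BA")):
        net.graph.nodes[nid[k]]["kind"] = "inlet"
        net.graph.nodes[nid[k]]["label"] = lbl

    # --- outlet allocation over the six trunks ------------------------------
    counts = [0] * len(_TRUNKS)
    for i in range(n_outlets):
        counts[i % len(_TRUNKS)] += 1

    # --- distal trees --------------------------------------------------------
    trunk_root_radius: dict[str, float] = {}

    # segments must be a few radii long or 3D thinning collapses them at
    # the tips; the per-subtree Murray radius estimate sets a length floor
    leaf_cap = max(leaf_radius_range[1], min_radius or 0.0)
    cone_half_angle = np.deg2rad(26.0)

    def _seg_length(level, k_leaves):
        base = s * 3.6 * (0.82 ** level) * rng.uniform(0.9, 1.1)
        return max(base, 3.6 * np.cbrt(k_leaves) * leaf_cap)

    def _cap_directions(d, k):
        """k area-uniform Fibonacci directions on a spherical cap around d."""
        d = _unit(d)
        if k == 1:
            return [d]
        e1, e2 = _perp_basis(d)
        golden = np.pi * (3.0 - np.sqrt(5.0))
        dirs = []
        for i in range(k):
            frac = (i + 0.5) / k
            ct = 1.0 - frac * (1.0 - np.cos(cone_half_angle))
            st = np.sqrt(max(1.0 - ct * ct, 0.0))
            phi = i * golden + rng.uniform(-0.05, 0.05)
            dirs.append(ct * d + st * (np.cos(phi) * e1 + np.sin(phi) * e2))
        return dirs

    min_split_angle = np.deg2rad(46.0)

    def _enforce_angle(d1, d2):
        """Push two child directions apart to the minimum split angle so
        sibling tubes do not merge when rasterized."""
        ang = np.arccos(np.clip(d1 @ d2, -1.0, 1.0))
        if ang >= min_split_angle:
            return d1, d2
        m = _unit(d1 + d2)
        p = d1 - (d1 @ m) * m
        if np.linalg.norm(p) < 1e-8:
            p = _perp_basis(m)[0]
        p = _unit(p)
        h = 0.5 * min_split_angle
        return (_unit(np.cos(h) * m + np.sin(h) * p),
                _unit(np.cos(h) * m - np.sin(h) * p))

    def grow(root_id, trunk_dir, leaf_dirs, branch, level, own_dir=None):
        """Grow toward the leaf directions; return the Murray root radius."""
        k = len(leaf_dirs)
        if k == 1:
            r = rng.uniform(*leaf_radius_range)
            if min_radius is not None:
                r = max(r, min_radius)
            length = max(s * 3.6 * (0.82 ** level) * rng.uniform(0.9, 1.1), 5.5 * r)
            d = leaf_dirs[0] if own_dir is None else own_dir
            tip = net.position(root_id) + d * length
            out = b.node(tip, kind="outlet", label="")
            b.edge(root_id, out, radius=r, branch=branch)
            return r
        # split the leaf bundle into two contiguous azimuthal sectors
        e1, e2 = _perp_basis(trunk_dir)
        phis = [np.arctan2(ld @ e2, ld @ e1) for ld in leaf_dirs]
        order = np.argsort(phis)
        k1 = (k + 1) // 2
        halves = [[leaf_dirs[i] for i in order[:k1]],
                  [leaf_dirs[i] for i in order[k1:]]]
        cds = [_unit(np.mean(sub, axis=0)) for sub in halves]
        cds = list(_enforce_angle(*cds))
        radii = []
        for sub, cd in zip(halves, cds):
            child = b.node(net.position(root_id) + cd * _seg_length(level, len(sub)),
                           kind="junction")
            r_child = grow(child, trunk_dir, sub, branch, level + 1, own_dir=cd)
            b.edge(root_id, child, radius=r_child, branch=branch)
            radii.append(r_child)
        return float(np.cbrt(np.sum(np.asarray(radii) ** 3)))

    for (branch, _inlet, site, direction), k in zip(_TRUNKS, counts):
        if k == 0:
            trunk_root_radius[branch] = 0.0
            continue
        trunk_root_radius[branch] = grow(nid[site], _unit(direction),
                                         _cap_directions(direction, k), branch, 0)

    def murray(*radii):
        return float(np.cbrt(np.sum(np.asarray(radii, dtype=float) ** 3)))

    r_comm = max(0.62, min_radius or 0.0)
    r_m1l = max(trunk_root_radius["MCAl"], r_comm)
    r_m1r = max(trunk_root_radius["MCAr"], r_comm)
    r_a2l = max(trunk_root_radius["ACAl"], r_comm)
    r_a2r = max(trunk_root_radius["ACAr"], r_comm)
    r_p2l = max(trunk_root_radius["PCAl"], r_comm)
    r_p2r = max(trunk_root_radius["PCAr"], r_comm)
    r_a1l, r_a1r = murray(r_a2l, r_comm), murray(r_a2r, r_comm)
    r_p1l, r_p1r = murray(r_p2l, r_comm), murray(r_p2r, r_comm)
    r_ica_l = murray(r_m1l, r_a1l)
    r_ica_r = murray(r_m1r, r_a1r)
    r_ba = murray(r_p1l, r_p1r)

    # ring + inlet edges (branch labels name the field's segment names)
    b.edge(nid["ica_in_l"], nid["ica_term_l"], r_ica_l, branch="ICAl")
    b.edge(nid["ica_in_r"], nid["ica_term_r"], r_ica_r, branch="ICAr")
    b.edge(nid["ba_in"], nid["bas_tip"], r_ba, branch="BA")
    b.edge(nid["bas_tip"], nid["pca_j_l"], r_p1l, branch="P1l")
    b.edge(nid["bas_tip"], nid["pca_j_r"], r_p1r, branch="P1r")
    b.edge(nid["ica_term_l"], nid["aca_mca_l"], r_m1l, branch="M1l")
    b.edge(nid["ica_term_r"], nid["aca_mca_r"], r_m1r, branch="M1r")
    b.edge(nid["ica_term_l"], nid["aca_root_l"], r_a1l, branch="A1l")
    b.edge(nid["ica_term_r"], nid["aca_root_r"], r_a1r, branch="A1r")
    b.edge(nid["aca_root_l"], nid["aca_root_r"], r_comm, branch="Acom")
    b.edge(nid["ica_term_l"], nid["pca_j_l"], r_comm, branch="Pcoml")
    b.edge(nid["ica_term_r"], nid["pca_j_r"], r_comm, branch="Pcomr")

    # drop ring nodes that ended up unused (trunks with zero outlets keep
    # their ring attachment; it simply stays a junction on the loop)
    net.metadata["branch_to_inlet"] = {t[0]: t[1] for t in _TRUNKS}
    net.validate(cow_template=True)
    assert len(net.outlets) == n_outlets
    return net


def generate_trunk_template(n_side_outlets: int = 4, seed: int = 0, *,
                            trunk_radius: float = 2.0,
                            side_radius: float = 1.0,
                            segment_length: float = 8.0,
                            side_length: float = 5.0) -> VesselNetwork:
    """Single trunk with side offtakes and one distal main outlet.

    This is the minimal geometry on which trimming (removing side outlets
    while keeping the distal main outlet) must overestimate distal flow.
    """
    if n_side_outlets < 1:
        raise InvalidArgumentError("need at least one side outlet")
    rng = np.random.default_rng(seed)
    net = VesselNetwork(metadata={"provenance": "cowflow trunk template", "units": "mm"})
    b = _Builder(net)
    inlet = b.node([0, 0, 0], kind="inlet", label="IN")
    prev = inlet
    x = 0.0
    for i in range(n_side_outlets):
        x += segment_length
        j = b.node([x, 0, 0], kind="junction")
        b.edge(prev, j, trunk_radius, branch="trunk")
        ang = 2.399963 * i + rng.uniform(-0.1, 0.1)  # golden-angle spread
        off = np.array([0.2, np.cos(ang), np.sin(ang)])
        o = b.node(np.array([x, 0, 0]) + _unit(off) * side_length,
                   kind="outlet", label=f"side{i}")
        b.edge(j, o, side_radius, branch=f"side{i}")
        prev = j
    x += segment_length
    main = b.node([x, 0, 0], kind="outlet", label="main")
    b.edge(prev, main, trunk_radius, branch="trunk")
    net.validate()
    return net


def straight_tube_network(radius: float = 2.0, length: float = 20.0) -> VesselNetwork:
    """One inlet, one outlet, one straight edge — the basic test geometry."""
    net = VesselNetwork(metadata={"provenance": "cowflow straight tube", "units": "mm"})
    b = _Builder(net)
    a = b.node([0, 0, 0], kind="inlet", label="IN")
    c = b.node([length, 0, 0], kind="outlet", label="OUT")
    b.edge(a, c, radius, branch="tube")
    return net


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def rasterize_network(network: VesselNetwork, spacing: float = 0.32,
                      lumen_intensity: float = 100.0,
                      background_intensity: float = 0.0,
                      noise_sd: float = 0.0, seed: int = 0, *,
                      pad: float = 2.0, supersample: int = 3,
                      voxel_budget: int = 40_000_000,
                      rician: bool = False) -> tuple[ImageVolume, GroundTruth]:
    """Voxelize the network as a bright tubular lumen on a darker background.

    Each vessel edge is treated as a capsule (cylinder with hemispherical
    caps) of its radius around the straight centerline.  The lumen
    indicator is super-sampled ``supersample``× per axis and box-averaged,
    which yields sub-voxel partial-volume mixing at the wall; optional
    additive Gaussian noise (or Rician, via ``rician=True``) is then added.
    The returned :class:`GroundTruth` mask is the exact noise-free lumen
    indicator (occupancy >= 0.5).
    """
    if spacing <= 0:
        raise InvalidArgumentError("spacing must be > 0")
    if lumen_intensity <= background_intensity:
        raise InvalidArgumentError("lumen intensity must exceed background intensity")
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")

    nodes = np.array([network.position(n) for n in network.graph.nodes])
    radii = [d["radius"] for _, _, d in network.graph.edges(data=True)]
    rmax = max(radii)
    lo = nodes.min(axis=0) - rmax - pad
    hi = nodes.max(axis=0) + rmax + pad
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 16)
    n_vox = int(np.prod(shape))
    if n_vox > voxel_budget:
        raise ResourceLimitError(
            f"grid {tuple(shape)} = {n_vox} voxels exceeds the voxel budget "
            f"of {voxel_budget}; coarsen the spacing or shrink the network")
    origin = lo

    ss = int(supersample)
    ss_shape = shape * ss
    inside = np.zeros(ss_shape, dtype=bool)

    def sub_axis(n):
        # world coordinate of sub-voxel centres along one axis
        j = np.arange(n)
        return (j - (ss - 1) / 2.0) / ss * spacing

    axes_w = [origin[a] + sub_axis(ss_shape[a]) for a in range(3)]

    edges = sorted(network.graph.edges(keys=True, data=True), key=lambda e: e[2])
    for u, v, _k, d in edges:
        a = network.position(u)
        c = network.position(v)
        r = d["radius"]
        blo = np.minimum(a, c) - r - spacing
        bhi = np.maximum(a, c) + r + spacing
        sl = []
        for ax in range(3):
            i0 = int(np.searchsorted(axes_w[ax], blo[ax]))
            i1 = int(np.searchsorted(axes_w[ax], bhi[ax]))
            sl.append(slice(max(i0 - 1, 0), min(i1 + 1, ss_shape[ax])))
        X = axes_w[0][sl[0]][:, None, None]
        Y = axes_w[1][sl[1]][None, :, None]
        Z = axes_w[2][sl[2]][None, None, :]
        ab = c - a
        denom = float(np.dot(ab, ab))
        px, py, pz = X - a[0], Y - a[1], Z - a[2]
        t = (px * ab[0] + py * ab[1] + pz * ab[2]) / denom
        t = np.clip(t, 0.0, 1.0)
        dx = px - t * ab[0]
        dy = py - t * ab[1]
        dz = pz - t * ab[2]
        inside[sl[0], sl[1], sl[2]] |= (dx * dx + dy * dy + dz * dz) <= r * r

    occ = inside.reshape(shape[0], ss, shape[1], ss, shape[2], ss) \
                .mean(axis=(1, 3, 5), dtype=np.float32)
    del inside

    data = background_intensity + (lumen_intensity - background_intensity) * \
        occ.astype(np.float64)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        if rician:
            n1 = rng.normal(0.0, noise_sd, size=data.shape)
            n2 = rng.normal(0.0, noise_sd, size=data.shape)
            data = np.sqrt((data + n1) ** 2 + n2 ** 2)
        else:
            data = data + rng.normal(0.0, noise_sd, size=data.shape)

    volume = ImageVolume(data=data, spacing=spacing, origin=origin)
    mask = occ >= 0.5

    centerlines = []
    gt_radii = {}
    for u, v, k, d in edges:
        a, c, r = network.position(u), network.position(v), d["radius"]
        L = float(np.linalg.norm(c - a))
        clip = min(max(spacing, 0.4 * r), 0.45 * L)
        n_pts = max(int(np.ceil(L / (spacing / 2.0))), 2)
        tt = np.linspace(clip / L, 1 - clip / L, n_pts)
        centerlines.append((k, a[None, :] + tt[:, None] * (c - a)[None, :]))
        gt_radii[k] = r

    openings = []
    for n in network.inlets + network.outlets:
        (nbr,) = list(network.graph.neighbors(n))
        direction = _unit(network.position(n) - network.position(nbr))
        edata = next(iter(network.graph.get_edge_data(n, nbr).values()))
        openings.append({
            "id": n,
            "label": network.graph.nodes[n].get("label") or n,
            "kind": network.node_kind(n),
            "position": network.position(n).tolist(),
            "direction": direction.tolist(),
            "radius_mm": edata["radius"],
        })

    gt = GroundTruth(mask=mask, centerlines=centerlines, radii=gt_radii,
                     openings=openings)
    return volume, gt


# ---------------------------------------------------------------------------
# inlet waveforms
# ---------------------------------------------------------------------------

# Fixed truncated-Fourier cardiac shape: zero-mean harmonics with the
# systolic peak placed at 15% of the period.
_SHAPE_COEFFS = np.array([1.0, 0.45, 0.18, 0.06])
_PEAK_FRACTION = 0.15


def _cardiac_shape(phase: np.ndarray) -> np.ndarray:
    """Zero-mean periodic shape with minimum exactly -1."""
    x = 2 * np.pi * (phase - _PEAK_FRACTION)
    b = np.zeros_like(phase, dtype=float)
    for k, a in enumerate(_SHAPE_COEFFS, start=1):
        b += a * np.cos(k * x)
    fine = 2 * np.pi * (np.linspace(0, 1, 4096, endpoint=False) - _PEAK_FRACTION)
    bmin = sum(a * np.cos(k * fine) for k, a in enumerate(_SHAPE_COEFFS, 1)).min()
    return b / abs(bmin)


def generate_inflow_waveform(mean_flow: float, period: float = 1.0,
                             pulsatility: float = 0.5,
                             n_samples: int = 200,
                             label: str = "") -> FlowWaveform:
    """Smooth one-period inlet waveform (l/s) with exact time-average
    ``mean_flow`` and minimum ``mean_flow * (1 - pulsatility)``."""
    if mean_flow <= 0:
        raise InvalidArgumentError("mean_flow must be > 0")
    if period <= 0:
        raise InvalidArgumentError("period must be > 0")
    if not (0.0 <= pulsatility < 1.0):
        raise InvalidArgumentError(
            "pulsatility must lie in [0, 1) — reverse inlet flow is not modelled")
    if n_samples < 50:
        raise InvalidArgumentError("n_samples must be >= 50")
    phase = np.linspace(0.0, 1.0, n_samples)
    values = mean_flow * (1.0 + pulsatility * _cardiac_shape(phase))
    values[-1] = values[0]  # close the period exactly
    return FlowWaveform(period=period, values=values, label=label)


def default_inlet_waveforms(period: float = 1.0, pulsatility: float = 0.5,
                            n_samples: int = 200) -> dict[str, FlowWaveform]:
    """Waveforms for the three inlets at the reference mean flows."""
    return {lbl: generate_inflow_waveform(q, period, pulsatility, n_samples, label=lbl)
            for lbl, q in sorted(DEFAULT_INLET_MEAN_FLOWS.items())}


# ---------------------------------------------------------------------------
# aneurysm specification
# ---------------------------------------------------------------------------

def make_aneurysm_spec(network: VesselNetwork, edge_id: str,
                       arc_position: float = 0.5,
                       sac_volume: float = 100.0,
                       compliance: float = 1e-12, *,
                       neck_ratio: float = 1.0,
                       neck_length: float = 1.0,
                       label: str = "IA") -> AneurysmSpec:
    """Parametrize a saccular aneurysm on a vessel edge.  The neck radius is
    the parent edge radius scaled by ``neck_ratio`` (1.0 = diameter-matched)."""
    _u, _v, d = network.edge_by_id(edge_id)
    if d["kind"] != "vessel":
        raise InvalidArgumentError("cannot place an aneurysm on a neck edge")
    if not (0.0 < neck_ratio <= 1.0):
        raise InvalidArgumentError("neck_ratio must lie in (0, 1]")
    spec = AneurysmSpec(edge_id=edge_id, arc_position=arc_position,
                        neck_radius=neck_ratio * d["radius"],
                        sac_volume=sac_volume, compliance=compliance,
                        neck_length=neck_length, label=label)
    spec.validate(network)
    return spec
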