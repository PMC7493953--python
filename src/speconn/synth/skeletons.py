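"""Skeleton generation: somata, branching dendritic trees, and passing axons.

Geometry model
--------------
* Somata are spheres (radius drawn from ``soma_radius_um``), represented in
  SWC as a type-1 root at the center plus a shell of type-1 surface nodes
  (~1 um spacing) so that somatic synapses link to a nearby soma-type node.
* Dendrites are persistent random walks grown from the soma surface at a
  coarse step, branching with a per-length probability, then resampled to
  ``node_spacing_nm`` (<= half the smallest pitch).
* Axons (a thin type-2 branch per neuron, plus external axons entering
  through volume faces) are routed as polylines through *waypoints* planted
  at controlled distances from postsynaptic surfaces: close appositions at
  membrane-contact distance, and deliberate ~700 nm "near misses" that later
  serve as unlabeled-partner distractor sites.

All coordinates are (x, y, z) pre-expansion nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..types import SWC_AXON, SWC_DENDRITE, SWC_SOMA, Skeleton, SkeletonNode
from .config import SceneConfig

__all__ = ["generate_skeletons", "SceneError", "NEAR_MISS_OFFSET_NM"]

NEAR_MISS_OFFSET_NM = 700.0  # centerline-to-surface distance of a planted near miss


class SceneError(RuntimeError):
    """Raised when scene construction cannot satisfy its constraints."""


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector")
    return v / n


def _rand_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return _unit(v)


def _perp(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    u = rng.normal(size=3)
    u -= u.dot(v) * v
    return _unit(u)


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (deterministic)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1 - 2 * i / n
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


# ---------------------------------------------------------------------------
# soma placement
# ---------------------------------------------------------------------------

def _place_somata(config: SceneConfig, rng: np.random.Generator):
    sx, sy, sz = config.size_nm
    lo_r, hi_r = (r * 1000.0 for r in config.soma_radius_um)
    centers, radii = [], []
    for _ in range(config.n_neurons):
        placed = False
        for _attempt in range(4000):
            r = rng.uniform(lo_r, hi_r)
            margin = r + 800.0
            if sx < 2 * margin or sy < 2 * margin or sz < 2 * margin:
                break
            c = np.array([
                rng.uniform(margin, sx - margin),
                rng.uniform(margin, sy - margin),
                rng.uniform(margin, sz - margin),
            ])
            if all(np.linalg.norm(c - c2) >= r + r2 + 1500.0
                   for c2, r2 in zip(centers, radii)):
                centers.append(c)
                radii.append(r)
                placed = True
                break
        if not placed:
            raise SceneError(
                f"could not place {config.n_neurons} somata of radius "
                f"{config.soma_radius_um} um in a {config.size_um} um volume"
            )
    return np.array(centers), np.array(radii)


# ---------------------------------------------------------------------------
# node bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class _Builder:
    nodes: list
    next_id: int = 1

    def add(self, swc_type: int, pos, radius: float, parent: int) -> int:
        nid = self.next_id
        self.next_id += 1
        self.nodes.append(SkeletonNode(
            node_id=nid, swc_type=swc_type,
            position=(float(pos[0]), float(pos[1]), float(pos[2])),
            radius=float(radius), parent_id=parent,
        ))
        return nid

    def add_polyline(self, pts: np.ndarray, swc_type: int, radius: float,
                     parent: int) -> int:
        """Chain nodes along pts[1:], attached to ``parent`` (pts[0] is the
        parent's position and is not duplicated).  Returns last node id."""
        for p in pts[1:]:
            parent = self.add(swc_type, p, radius, parent)
        return parent


def _resample(poly: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline at uniform arc-length ``spacing`` (keeps endpoints)."""
    seg = np.diff(poly, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    keep = seglen > 1e-9
    poly = np.concatenate([poly[:1], poly[1:][keep]], axis=0)
    if len(poly) < 2:
        return poly
    seg = np.diff(poly, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    n = max(2, int(math.ceil(s[-1] / spacing)) + 1)
    si = np.linspace(0.0, s[-1], n)
    out = np.empty((n, 3))
    for d in range(3):
        out[:, d] = np.interp(si, s, poly[:, d])
    return out


# ---------------------------------------------------------------------------
# dendrites
# ---------------------------------------------------------------------------

def _grow_dendrites(builder: _Builder, center: np.ndarray, radius: float,
                    surface_ids: list[int], surface_dirs: np.ndarray,
                    somata: tuple[np.ndarray, np.ndarray],
                    config: SceneConfig, rng: np.random.Generator) -> None:
    sx, sy, sz = config.size_nm
    step = 2000.0  # coarse growth step, nm
    budget = config.dendrite_total_um * 1000.0
    n_stems = int(rng.integers(config.n_stems[0], config.n_stems[1] + 1))
    centers_all, radii_all = somata

    # stems leave the soma in well-separated directions
    stem_dirs = []
    for _ in range(n_stems):
        for _a in range(100):
            d = _rand_unit(rng)
            if all(d.dot(e) < 0.6 for e in stem_dirs):
                break
        stem_dirs.append(d)

    # each stem starts at the nearest soma surface node
    queue = []  # (start_pos, direction, parent_node_id, remaining_len)
    for d in stem_dirs:
        k = int(np.argmax(surface_dirs @ d))
        start = center + radius * surface_dirs[k]
        queue.append((start, d.copy(), surface_ids[k], rng.uniform(40e3, 80e3)))

    grown = 0.0
    while queue and grown < budget:
        pos, direction, parent, remaining = queue.pop(0)
        coarse = [pos.copy()]
        length = 0.0
        while length < remaining and grown < budget:
            direction = _unit(direction + 0.30 * rng.normal(size=3))
            nxt = pos + direction * step
            # steer off the volume boundary
            for ax, size in enumerate((sx, sy, sz)):
                if nxt[ax] < 1000.0 and direction[ax] < 0:
                    direction[ax] *= -1
                elif nxt[ax] > size - 1000.0 and direction[ax] > 0:
                    direction[ax] *= -1
            direction = _unit(direction)
            nxt = pos + direction * step
            # deflect out of other somata
            for c2, r2 in zip(centers_all, radii_all):
                v = nxt - c2
                d2 = np.linalg.norm(v)
                if d2 < r2 + 800.0 and d2 > 0:
                    nxt = c2 + v / d2 * (r2 + 800.0)
                    direction = _unit(nxt - pos)
            pos = nxt
            coarse.append(pos.copy())
            length += step
            grown += step
            if rng.random() < config.branch_prob_per_um * step / 1000.0:
                # spawn a sibling branch from this point
                alpha = rng.uniform(0.6, 1.0)  # ~35-60 degrees
                u = _perp(direction, rng)
                child_dir = _unit(math.cos(alpha) * direction + math.sin(alpha) * u)
                queue.append((pos.copy(), child_dir,
                              -1,  # placeholder, fixed below via coarse chaining
                              rng.uniform(20e3, 50e3)))
                # remember where to attach: store index of coarse point
                queue[-1] = (pos.copy(), child_dir, ("pending", len(coarse) - 1), queue[-1][3])
        fine = _resample(np.array(coarse), config.node_spacing_nm)
        # map pending children to real node ids as we create them
        created_ids = [None] * len(coarse)
        if isinstance(parent, tuple):
            raise AssertionError("stem parent must be a node id")
        # create nodes and record the id nearest to each coarse vertex
        seg = np.diff(np.array(coarse), axis=0)
        cum = np.concatenate([[0.0], np.cumsum(np.linalg.norm(seg, axis=1))])
        fine_seg = np.diff(fine, axis=0)
        fine_cum = np.concatenate([[0.0], np.cumsum(np.linalg.norm(fine_seg, axis=1))])
        last = parent
        ci = 0
        created_ids[0] = parent
        for i, p in enumerate(fine[1:], start=1):
            last = builder.add(SWC_DENDRITE, p, config.dendrite_radius_nm, last)
            while ci + 1 < len(cum) and fine_cum[i] >= cum[ci + 1] - 1e-6:
                ci += 1
                created_ids[ci] = last
        for j, item in enumerate(queue):
            if isinstance(item[2], tuple) and item[2][0] == "pending":
                k = item[2][1]
                if k < len(created_ids) and created_ids[k] is not None:
                    queue[j] = (item[0], item[1], created_ids[k], item[3])
        # drop any child whose attachment never materialized
        queue = [it for it in queue if not isinstance(it[2], tuple)]


# ---------------------------------------------------------------------------
# axon waypoints and routing
# ---------------------------------------------------------------------------

def _contact_waypoint(neurons_geo, config, rng, offset_nm, exclude=None):
    """A point at ``offset_nm`` beyond a random postsynaptic surface.

    Returns (waypoint, post_index) or None if no clean site was found.
    ``neurons_geo`` is a list of dicts with center, radius, dendrite node
    positions (cumulative arrays) per neuron.
    """
    for _ in range(60):
        j = int(rng.integers(len(neurons_geo)))
        if exclude is not None and j == exclude:
            continue
        geo = neurons_geo[j]
        if rng.random() < config.somatic_fraction or len(geo["dend"]) == 0:
            d = _rand_unit(rng)
            surface = geo["center"] + geo["radius"] * d
            # keep somatic sites clear of dendritic stems for crisp compartments
            if len(geo["dend"]):
                if np.min(np.linalg.norm(geo["dend"] - surface, axis=1)) < 1500.0:
                    continue
            return surface + offset_nm * d, j
        else:
            k = int(rng.integers(len(geo["dend"])))
            p = geo["dend"][k]
            # skip proximal dendrite (close to the soma surface)
            if np.linalg.norm(p - geo["center"]) < geo["radius"] + 1500.0:
                continue
            tangent = geo["dend_tangent"][k]
            n_hat = _perp(tangent, rng)
            return p + (config.dendrite_radius_nm + offset_nm) * n_hat, j
    return None


def _route(points: list[np.ndarray], somata, axon_r: float) -> np.ndarray:
    """Polyline through ``points`` with soma-interior avoidance."""
    centers, radii = somata
    pts = [np.asarray(p, dtype=float) for p in points]
    out = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        seg = b - a
        L = np.linalg.norm(seg)
        if L > 1e-9:
            for c, r in zip(centers, radii):
                t = np.clip((c - a).dot(seg) / (L * L), 0.0, 1.0)
                if t in (0.0, 1.0):
                    continue
                q = a + t * seg
                v = q - c
                d = np.linalg.norm(v)
                if d < r:  # passes through the soma interior: graze instead
                    q_new = c + (v / d if d > 0 else _unit(seg + 1.0)) * (r + axon_r + 20.0)
                    out.append(q_new)
        out.append(b)
    return np.array(out)


def _face_point(p: np.ndarray, size_nm, rng=None) -> np.ndarray:
    """Project p to the nearest volume face."""
    q = p.copy()
    dists = []
    for ax, s in enumerate(size_nm):
        dists.append((p[ax], ax, 0.0))
        dists.append((s - p[ax], ax, s))
    _, ax, val = min(dists)
    q[ax] = val
    return q


def _random_face_point(size_nm, rng) -> np.ndarray:
    ax = int(rng.integers(3))
    p = np.array([rng.uniform(0.1 * s, 0.9 * s) for s in size_nm])
    p[ax] = 0.0 if rng.random() < 0.5 else size_nm[ax]
    return p


def _tour(entry: np.ndarray, waypoints: list[np.ndarray]) -> list[np.ndarray]:
    """Greedy nearest-neighbor ordering starting from entry."""
    rest = [np.asarray(w) for w in waypoints]
    out = [entry]
    cur = entry
    while rest:
        i = int(np.argmin([np.linalg.norm(w - cur) for w in rest]))
        cur = rest.pop(i)
        out.append(cur)
    return out


# ---------------------------------------------------------------------------
# public entry point
# ---------------------------------------------------------------------------

def generate_skeletons(config: SceneConfig, seed: int | np.random.Generator) -> list[Skeleton]:
    """Generate neuron and external-axon skeletons for a scene.

    Deterministic given (config, seed).  Neurons are named ``N1..``, external
    axons ``A1..``.  Each neuron carries soma (type 1), dendrites (type 3)
    and one thin axon (type 2); external axons are type-2 chains entering and
    leaving through volume faces.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centers, radii = _place_somata(config, rng)
    size_nm = config.size_nm

    skeletons: list[Skeleton] = []
    builders: list[_Builder] = []
    # pass 1: somata + dendrites
    for i in range(config.n_neurons):
        b = _Builder(nodes=[])
        root = b.add(SWC_SOMA, centers[i], radii[i], -1)
        n_surf = max(12, int(4 * math.pi * radii[i] ** 2 / 1000.0 ** 2))
        dirs = fibonacci_sphere(n_surf)
        surf_ids = [b.add(SWC_SOMA, centers[i] + radii[i] * d, 400.0, root) for d in dirs]
        _grow_dendrites(b, centers[i], radii[i], surf_ids, dirs,
                        (centers, radii), config, rng)
        builders.append(b)

    # geometry summaries used for waypoint planting
    neurons_geo = []
    for i, b in enumerate(builders):
        dend = np.array([n.position for n in b.nodes if n.swc_type == SWC_DENDRITE])
        if len(dend) >= 2:
            tang = np.empty_like(dend)
            tang[1:] = dend[1:] - dend[:-1]
            tang[0] = tang[1]
            norms = np.linalg.norm(tang, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            tang /= norms
        else:
            dend = np.empty((0, 3))
            tang = np.empty((0, 3))
        neurons_geo.append({
            "center": centers[i], "radius": radii[i],
            "dend": dend, "dend_tangent": tang,
        })

    contact_offset = config.axon_radius_nm + config.cleft_nm

    # pass 2: one axon per neuron, visiting a couple of other neurons
    for i, b in enumerate(builders):
        start_dir = _rand_unit(rng)
        start = centers[i] + radii[i] * start_dir
        # attach at nearest surface node
        surf_nodes = [n for n in b.nodes if n.swc_type == SWC_SOMA and n.parent_id != -1]
        sp = np.array([n.position for n in surf_nodes])
        attach = surf_nodes[int(np.argmin(np.linalg.norm(sp - start, axis=1)))]
        wps = []
        for _ in range(config.contacts_per_neuron_axon):
            w = _contact_waypoint(neurons_geo, config, rng, contact_offset, exclude=i)
            if w is not None:
                wps.append(w[0])
        pts = _tour(np.array(attach.position, dtype=float), wps)
        pts.append(_face_point(pts[-1], size_nm))
        poly = _route(pts, (centers, radii), config.axon_radius_nm)
        fine = _resample(poly, config.node_spacing_nm)
        b.add_polyline(fine, SWC_AXON, config.axon_radius_nm, attach.node_id)
        skeletons.append(Skeleton(neuron_id=f"N{i+1}", nodes=b.nodes, label="PV"))

    # pass 3: external axons
    for a in range(config.n_external_axons):
        b = _Builder(nodes=[])
        entry = _random_face_point(size_nm, rng)
        wps = []
        for _ in range(config.contacts_per_axon):
            w = _contact_waypoint(neurons_geo, config, rng, contact_offset)
            if w is not None:
                wps.append(w[0])
        for _ in range(config.near_miss_per_axon):
            w = _contact_waypoint(neurons_geo, config, rng, NEAR_MISS_OFFSET_NM)
            if w is not None:
                wps.append(w[0])
        pts = _tour(entry, wps)
        pts.append(_face_point(pts[-1], size_nm))
        poly = _route(pts, (centers, radii), config.axon_radius_nm)
        fine = _resample(poly, config.node_spacing_nm)
        root = b.add(SWC_AXON, fine[0], config.axon_radius_nm, -1)
        b.add_polyline(fine, SWC_AXON, config.axon_radius_nm, root)
        skeletons.append(Skeleton(neuron_id=f"A{a+1}", nodes=b.nodes, label="axon"))

    return skeletons
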