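"""Scene assembly: apposition discovery, synapse planting, multi-round
simulation, and the all-in-one :func:`build_scene`.

Planting model
--------------
A putative synapse lives at an *apposition*: a labeled axon passing within
contact distance of a postsynaptic soma or dendrite membrane.  The PSD
punctum (Gephyrin for inhibitory, Homer1 for excitatory) is centered on the
post membrane surface; the Bassoon punctum is displaced along the local
contact normal toward the axon by a separation drawn from a truncated normal
(mean 150 nm, clipped to 100-200 nm).  A small configured fraction of
Bassoon puncta are planted unpaired (orphans).  Two distractor classes are
planted alongside: appositions with *no* machinery, and pairs whose true
presynaptic axon is unlabeled while a labeled axon passes nearby.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ..types import (SWC_AXON, SWC_DENDRITE, SWC_SOMA, Skeleton,
                     SynapseRecord, VoxelGrid)
from ..transforms import SinusoidalWarp, resample_through
from .config import GroundTruth, SceneConfig
from .render import (FIDUCIAL_CHANNEL, FP_CHANNELS, PUNCTA_CHANNELS,
                     apply_noise, render_blobs, render_fiducial, render_scene)
from .colors import assign_colors
from .skeletons import SceneError, generate_skeletons

__all__ = ["find_appositions", "plant_synapses", "simulate_rounds",
           "build_scene", "generate_puncta_field", "SceneBundle", "ContactSite"]


@dataclass
class ContactSite:
    axon_id: str
    post_id: str
    post_node_id: int
    surface_xyz: np.ndarray
    normal: np.ndarray          # outward from post surface toward the axon
    axon_xyz: np.ndarray
    axon_tangent: np.ndarray
    compartment: str            # somatic | dendritic
    surface_dist_nm: float      # post surface to axon centerline


def _runs(mask: np.ndarray):
    """Start/end indices of contiguous True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if mask[0]:
        starts = [0] + starts
    if mask[-1]:
        ends = ends + [len(mask)]
    return list(zip(starts, ends))


def _axon_chains(skeletons: list[Skeleton]):
    """(pre_id, positions (n,3) in chain order, own_neuron_or_None)."""
    chains = []
    for sk in skeletons:
        ax = [n for n in sk.nodes if n.swc_type == SWC_AXON]
        if not ax:
            continue
        pos = np.array([n.position for n in ax])
        own = sk.neuron_id if sk.has_soma else None
        chains.append((sk.neuron_id, pos, own))
    return chains


def find_appositions(skeletons: list[Skeleton], config: SceneConfig):
    """Discover close contacts and ~700 nm near misses geometrically.

    Returns ``(close_sites, nearmiss_sites)`` as lists of :class:`ContactSite`.
    """
    posts = [sk for sk in skeletons if sk.has_soma]
    centers = np.array([sk.root.position for sk in posts])
    radii = np.array([sk.root.radius for sk in posts])
    soma_nodes = [sk.nodes_of_type(SWC_SOMA) for sk in posts]
    soma_trees = [cKDTree(np.array([n.position for n in nodes])) for nodes in soma_nodes]

    dend_pos, dend_post, dend_nid, dend_rad = [], [], [], []
    for j, sk in enumerate(posts):
        for n in sk.nodes_of_type(SWC_DENDRITE):
            dend_pos.append(n.position)
            dend_post.append(j)
            dend_nid.append(n.node_id)
            dend_rad.append(n.radius)
    dend_pos = np.array(dend_pos) if dend_pos else np.empty((0, 3))
    dend_post = np.array(dend_post, dtype=int)
    dend_nid = np.array(dend_nid, dtype=int)
    dend_rad = np.array(dend_rad, dtype=float)
    dend_tree = cKDTree(dend_pos) if len(dend_pos) else None

    contact = config.axon_radius_nm + config.cleft_nm
    close, nearmiss = [], []

    for pre_id, P, own in _axon_chains(skeletons):
        tang = np.empty_like(P)
        tang[1:] = P[1:] - P[:-1]
        tang[0] = tang[1] if len(P) > 1 else [1.0, 0.0, 0.0]
        nrm = np.linalg.norm(tang, axis=1, keepdims=True)
        nrm[nrm == 0] = 1.0
        tang = tang / nrm

        # --- soma contacts and near misses
        for j in range(len(posts)):
            if posts[j].neuron_id == own:
                continue
            d = np.linalg.norm(P - centers[j], axis=1) - radii[j]  # surface dist
            for lo, hi, kind in ((contact - 60, contact + 60, "close"),
                                 (680.0, 900.0, "nearmiss")):
                for s, e in _runs((d >= lo) & (d <= hi)):
                    k = s + int(np.argmin(d[s:e]))
                    p = P[k]
                    direction = (p - centers[j])
                    direction = direction / np.linalg.norm(direction)
                    surface = centers[j] + radii[j] * direction
                    # keep somatic sites away from dendritic stems
                    if dend_tree is not None:
                        dd, ii = dend_tree.query(surface)
                        if dend_post[ii] == j and dd < 1200.0:
                            continue
                    nn_soma = soma_trees[j].query(surface)[1]
                    site = ContactSite(
                        axon_id=pre_id, post_id=posts[j].neuron_id,
                        post_node_id=soma_nodes[j][nn_soma].node_id,
                        surface_xyz=surface, normal=direction, axon_xyz=p,
                        axon_tangent=tang[k], compartment="somatic",
                        surface_dist_nm=float(d[k]),
                    )
                    (close if kind == "close" else nearmiss).append(site)

        # --- dendrite contacts
        if dend_tree is not None and len(P):
            dd, ii = dend_tree.query(P)
            surf = dd - dend_rad[ii]
            ok = (surf >= contact - 60) & (surf <= contact + 80)
            if own is not None:
                ok &= np.array([posts[q].neuron_id != own for q in dend_post[ii]])
            # split runs so one run stays on one post dendrite node cluster
            for s, e in _runs(ok):
                k = s + int(np.argmin(surf[s:e]))
                dn = ii[k]
                p = P[k]
                direction = p - dend_pos[dn]
                nlen = np.linalg.norm(direction)
                if nlen < 1e-9:
                    continue
                direction = direction / nlen
                surface = dend_pos[dn] + dend_rad[dn] * direction
                close.append(ContactSite(
                    axon_id=pre_id, post_id=posts[dend_post[dn]].neuron_id,
                    post_node_id=int(dend_nid[dn]),
                    surface_xyz=surface, normal=direction, axon_xyz=p,
                    axon_tangent=tang[k], compartment="dendritic",
                    surface_dist_nm=float(surf[k]),
                ))
    return close, nearmiss


# ---------------------------------------------------------------------------
# synapse planting
# ---------------------------------------------------------------------------

def _truncnorm(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size)
        good = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(good), size - filled)
        out[filled:filled + take] = good[:take]
        filled += take
    return out


def _psd_sigma_nm(volume_um3: float) -> float:
    """Blob sigma from the planted PSD volume (effective-sphere radius)."""
    r_eff = (3.0 * volume_um3 * 1e9 / (4.0 * math.pi)) ** (1.0 / 3.0)
    return float(np.clip(0.7 * r_eff, 70.0, 150.0))

BASSOON_SIGMA_NM = 90.0


def plant_synapses(skeletons: list[Skeleton], config: SceneConfig,
                   seed: int | np.random.Generator):
    """Plant synaptic machinery at appositions; returns ``(puncta_grid, gt)``.

    ``puncta_grid`` holds the Bassoon/Gephyrin/Homer1 channels (noise-free);
    ``gt`` is the :class:`GroundTruth` with every planted object.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    close, nearmiss = find_appositions(skeletons, config)
    if len(close) < config.n_synapses + config.n_distractor_contact:
        raise SceneError(
            f"only {len(close)} appositions available for "
            f"{config.n_synapses} synapses + {config.n_distractor_contact} distractors"
        )
    order = rng.permutation(len(close))

    n_close_pairs = int(round(config.close_fraction * config.n_synapses))
    n_spaced = config.n_synapses - n_close_pairs

    planted_sites: list[ContactSite] = []
    planted_pos: list[np.ndarray] = []

    def far_enough(p, dist):
        return (not planted_pos
                or np.min(np.linalg.norm(np.array(planted_pos) - p, axis=1)) >= dist)

    spare_sites = []
    for oi in order:
        site = close[oi]
        if len(planted_sites) >= n_spaced:
            spare_sites.append(site)
            continue
        if far_enough(site.surface_xyz, config.min_spacing_nm):
            planted_sites.append(site)
            planted_pos.append(site.surface_xyz)
        else:
            spare_sites.append(site)
    if len(planted_sites) < n_spaced:
        raise SceneError(
            "cannot satisfy the >=300 nm inter-synapse spacing rule: "
            f"placed {len(planted_sites)} of {n_spaced} spaced synapses"
        )

    # deliberately close siblings: a second synapse within the same bouton
    for _ in range(n_close_pairs):
        base = planted_sites[int(rng.integers(len(planted_sites)))]
        t = base.axon_tangent - base.axon_tangent.dot(base.normal) * base.normal
        tl = np.linalg.norm(t)
        if tl < 1e-6:
            continue
        t = t / tl
        delta = rng.uniform(180.0, 290.0)
        post = next(sk for sk in skeletons if sk.neuron_id == base.post_id)
        node_id = base.post_node_id
        if base.compartment == "somatic":
            c = np.asarray(post.root.position)
            r = post.root.radius
            v = (base.surface_xyz + delta * t) - c
            surface = c + r * v / np.linalg.norm(v)
            normal = v / np.linalg.norm(v)
        else:
            # re-project the shifted point onto the curving dendrite tube
            dnodes = post.nodes_of_type(SWC_DENDRITE)
            dpos = np.array([nd.position for nd in dnodes])
            shifted = base.surface_xyz + delta * t
            k = int(np.argmin(np.linalg.norm(dpos - shifted, axis=1)))
            v = shifted - dpos[k]
            vl = np.linalg.norm(v)
            if vl < 1e-6:
                continue
            normal = v / vl
            surface = dpos[k] + dnodes[k].radius * normal
            node_id = dnodes[k].node_id
        planted_sites.append(ContactSite(
            axon_id=base.axon_id, post_id=base.post_id,
            post_node_id=node_id, surface_xyz=surface, normal=normal,
            axon_xyz=base.axon_xyz + delta * t, axon_tangent=base.axon_tangent,
            compartment=base.compartment, surface_dist_nm=base.surface_dist_nm,
        ))
        planted_pos.append(surface)

    n = len(planted_sites)
    kinds = rng.choice(3, size=n, p=list(config.mixture))  # 0 exc, 1 inh, 2 orphan
    seps = _truncnorm(rng, config.separation_mean_nm, config.separation_sd_nm,
                      *config.separation_range_nm, size=n)
    vols = rng.uniform(*config.psd_volume_um3, size=n)

    synapses: list[SynapseRecord] = []
    orphans = []
    blob_entries = []  # (channel, xyz, sigma, amplitude)
    for i, site in enumerate(planted_sites):
        psd_xyz = site.surface_xyz
        bassoon_xyz = site.surface_xyz + seps[i] * site.normal
        blob_entries.append(("Bassoon", bassoon_xyz, BASSOON_SIGMA_NM,
                             config.puncta_amplitude))
        if kinds[i] == 2:
            orphans.append(bassoon_xyz)
            continue
        kind = "excitatory" if kinds[i] == 0 else "inhibitory"
        psd_channel = "Homer1" if kind == "excitatory" else "Gephyrin"
        blob_entries.append((psd_channel, psd_xyz, _psd_sigma_nm(vols[i]),
                             config.puncta_amplitude))
        synapses.append(SynapseRecord(
            synapse_id=f"S{len(synapses)+1:03d}", kind=kind,
            position=tuple(psd_xyz), post_neuron_id=site.post_id,
            pre_axon_id=site.axon_id,
            gephyrin_or_homer_peak=tuple(psd_xyz),
            bassoon_peak=tuple(bassoon_xyz),
            compartment=site.compartment, psd_volume_um3=float(vols[i]),
            node_id=site.post_node_id,
        ))

    # distractor A: contacts with no machinery, well clear of real synapses
    distractors_contact = []
    for site in spare_sites:
        if len(distractors_contact) >= config.n_distractor_contact:
            break
        if far_enough(site.surface_xyz, 1000.0):
            distractors_contact.append({
                "axon_id": site.axon_id, "post_id": site.post_id,
                "xyz": tuple(site.surface_xyz), "compartment": site.compartment,
            })
            planted_pos.append(site.surface_xyz)
    if len(distractors_contact) < config.n_distractor_contact:
        raise SceneError("not enough clean appositions for contact distractors")

    # distractor B: pair belongs to an unlabeled axon; a labeled axon passes
    # nearby but the Bassoon punctum is outside its membrane envelope
    all_axon_pos = np.concatenate([P for _, P, _ in _axon_chains(skeletons)])
    axon_tree = cKDTree(all_axon_pos)
    envelope = (config.axon_radius_nm + config.membrane_thickness_nm
                + min(config.pitch_nm))
    distractors_unlabeled: list[SynapseRecord] = []
    nm_order = rng.permutation(len(nearmiss))
    for oi in nm_order:
        if len(distractors_unlabeled) >= config.n_distractor_unlabeled:
            break
        site = nearmiss[oi]
        sep = float(_truncnorm(rng, config.separation_mean_nm, config.separation_sd_nm,
                               *config.separation_range_nm, size=1)[0])
        psd_xyz = site.surface_xyz
        bassoon_xyz = psd_xyz + sep * site.normal
        if not far_enough(psd_xyz, config.min_spacing_nm):
            continue
        d_lab, _ = axon_tree.query(bassoon_xyz)
        if not (envelope + 60.0 < d_lab < 780.0):
            continue
        vol = float(rng.uniform(*config.psd_volume_um3))
        kind = "inhibitory" if rng.random() < 0.5 else "excitatory"
        psd_channel = "Gephyrin" if kind == "inhibitory" else "Homer1"
        blob_entries.append(("Bassoon", bassoon_xyz, BASSOON_SIGMA_NM,
                             config.puncta_amplitude))
        blob_entries.append((psd_channel, psd_xyz, _psd_sigma_nm(vol),
                             config.puncta_amplitude))
        distractors_unlabeled.append(SynapseRecord(
            synapse_id=f"U{len(distractors_unlabeled)+1:03d}", kind=kind,
            position=tuple(psd_xyz), post_neuron_id=site.post_id,
            pre_axon_id="unlabeled",
            gephyrin_or_homer_peak=tuple(psd_xyz), bassoon_peak=tuple(bassoon_xyz),
            compartment=site.compartment, psd_volume_um3=vol,
            node_id=site.post_node_id,
        ))
        planted_pos.append(psd_xyz)
    if len(distractors_unlabeled) < config.n_distractor_unlabeled:
        raise SceneError(
            f"only {len(distractors_unlabeled)} of {config.n_distractor_unlabeled} "
            "unlabeled-partner distractors could be placed"
        )

    # spacing sanity: the quoted >300 nm nearest-neighbor property must hold
    pos = np.array([s.position for s in synapses])
    if len(pos) >= 2:
        tree = cKDTree(pos)
        nn = tree.query(pos, k=2)[0][:, 1]
        frac = float(np.mean(nn > 300.0))
        if frac < 0.90:
            raise SceneError(
                f"spacing rule violated: only {frac:.2f} of synapses are >300 nm "
                "from their nearest neighbor"
            )

    # render the three puncta channels
    shape = config.grid_shape
    data = np.zeros((3,) + shape, dtype=np.float32)
    for ci, ch in enumerate(PUNCTA_CHANNELS):
        entries = [e for e in blob_entries if e[0] == ch]
        if entries:
            data[ci] = render_blobs(
                shape, config.pitch_nm,
                np.array([e[1] for e in entries]),
                np.array([e[2] for e in entries]),
                np.array([e[3] for e in entries]),
                psf_sigma_nm=config.psf_sigma_nm,
            )
    puncta = VoxelGrid(channels=list(PUNCTA_CHANNELS), data=data,
                       pitch_nm=config.pitch_nm,
                       expansion_factor=config.expansion_factor)

    gt = GroundTruth(
        config=config, skeletons=skeletons, synapses=synapses,
        orphan_bassoon_xyz=np.array(orphans) if orphans else np.empty((0, 3)),
        distractors_contact=distractors_contact,
        distractors_unlabeled=distractors_unlabeled,
        color_clusters={sk.neuron_id: getattr(sk, "color_cluster", -1)
                        for sk in skeletons},
        cluster_centers=np.empty((0, 3)),
        decay=config.decay,
    )
    return puncta, gt


# ---------------------------------------------------------------------------
# multi-round simulation
# ---------------------------------------------------------------------------

def _draw_round_warp(config: SceneConfig, rng: np.random.Generator) -> SinusoidalWarp:
    ax, ay, az = (math.radians(rng.uniform(-config.round_rotation_deg,
                                           config.round_rotation_deg))
                  for _ in range(3))
    def rot(a, axis):
        c, s = math.cos(a), math.sin(a)
        m = np.eye(3)
        i, j = [(1, 2), (0, 2), (0, 1)][axis]
        m[i, i] = c; m[j, j] = c; m[i, j] = -s; m[j, i] = s
        return m
    scales = rng.uniform(*config.round_scale_range, size=3)
    linear = rot(ax, 0) @ rot(ay, 1) @ rot(az, 2) @ np.diag(scales)
    pitch_xyz = np.array([config.pitch_nm[2], config.pitch_nm[1], config.pitch_nm[0]])
    trans = rng.uniform(-1, 1, size=3) * config.round_translation_vox * pitch_xyz
    size = np.array(config.size_nm)
    return SinusoidalWarp(
        linear=linear, translation_nm=trans, center_nm=size / 2,
        amplitude_nm=config.round_wobble_vox * pitch_xyz,
        period_nm=size / rng.uniform(1.0, 2.0, size=3),
        phase=rng.uniform(0, 2 * math.pi, size=3),
    )


def simulate_rounds(scene: VoxelGrid, config: SceneConfig,
                    seed: int | np.random.Generator,
                    ground_truth: GroundTruth | None = None) -> list[VoxelGrid]:
    """Simulate ``config.n_rounds`` imaging rounds of a (noise-free) scene.

    Round 1 is the scene itself; round k is resampled through a planted
    affine + sinusoidal warp, stain channels decayed by ``decay**(k-1)``,
    each round noised independently.  Planted warps are appended to
    ``ground_truth.round_warps`` when a ground truth is supplied.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rounds = []
    warps = [None]
    for k in range(1, config.n_rounds + 1):
        if k == 1:
            rk = scene.copy()
        else:
            warp = _draw_round_warp(config, rng)
            warps.append(warp)
            rk = resample_through(scene, warp)
            # content must survive the warp
            if float(rk.data.max()) <= 0 < float(scene.data.max()):
                raise SceneError(f"round {k}: planted transform moved all content out of volume")
        decay_k = config.decay ** (k - 1)
        for ci, name in enumerate(rk.channels):
            if name == FIDUCIAL_CHANNEL and not config.decay_fiducial:
                continue
            rk.data[ci] *= decay_k
        if config.noise.enabled:
            rk.data = apply_noise(rk.data, config.noise, rng)
        rk.round_id = k
        rounds.append(rk)
    if ground_truth is not None:
        ground_truth.round_warps = warps
    return rounds


# ---------------------------------------------------------------------------
# one-call scene builder
# ---------------------------------------------------------------------------

@dataclass
class SceneBundle:
    """A fully rendered single-round scene with its ground truth."""

    grid: VoxelGrid                 # FP1-3 + Bassoon/Gephyrin/Homer1 + fiducial
    skeletons: list[Skeleton]
    ground_truth: GroundTruth


def build_scene(config: SceneConfig, with_fiducial: bool = True,
                noise: bool | None = None) -> SceneBundle:
    """Generate skeletons, colors, rendering, planting and noise in one call.

    Deterministic given ``config`` (which includes the seed).  ``noise=None``
    follows ``config.noise.enabled``.
    """
    ss = np.random.SeedSequence(config.seed)
    r_skel, r_color, r_plant, r_fid, r_noise = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )
    skeletons = generate_skeletons(config, r_skel)
    centers = assign_colors(skeletons, config.n_color_clusters,
                            config.color_min_separation, r_color,
                            jitter=config.color_jitter)
    fp = render_scene(skeletons, config, seed=r_color, noise=False)
    puncta, gt = plant_synapses(skeletons, config, r_plant)
    gt.cluster_centers = centers
    channels = list(fp.channels) + list(puncta.channels)
    stacks = [fp.data, puncta.data]
    if with_fiducial:
        fid, fid_centers = render_fiducial(config, r_fid)
        channels.append(FIDUCIAL_CHANNEL)
        stacks.append(fid[None])
        gt.fiducial_centers_xyz = fid_centers
    data = np.concatenate(stacks, axis=0)
    grid = VoxelGrid(channels=channels, data=data, pitch_nm=config.pitch_nm,
                     expansion_factor=config.expansion_factor)
    use_noise = config.noise.enabled if noise is None else noise
    if use_noise:
        grid.data = apply_noise(grid.data, config.noise, r_noise)
    return SceneBundle(grid=grid, skeletons=skeletons, ground_truth=gt)


def generate_fiducial_pair(seed: int | np.random.Generator,
                           shape=(48, 160, 160), pitch_nm=(200.0, 75.0, 75.0),
                           n_blobs: int = 250,
                           translation_vox: float = 8.0,
                           rotation_deg: float = 2.5,
                           scale_range=(0.98, 1.04),
                           wobble_vox: float = 1.0,
                           noise: "NoiseConfig | None" = None):
    """A fiducial blob field and its warped second round, with ground truth.

    Returns ``(fixed, moving, blob_centers, warp)`` where ``warp`` is the
    planted round-1 -> round-2 pull-back map (round2(x) = round1(warp(x))).
    A registration estimate T is correct when T(c) matches the round-2
    position of a blob at c, i.e. warp^{-1}(c).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nz, ny, nx = shape
    pz, py, px = pitch_nm
    ext = np.array([(nx - 1) * px, (ny - 1) * py, (nz - 1) * pz])
    centers = np.stack([rng.uniform(800, e - 800, n_blobs) for e in ext], axis=1)
    psf = tuple(p / 2.3548 for p in pitch_nm)
    # blob size >= z pitch so the field is adequately sampled on all axes
    F = render_blobs(shape, pitch_nm, centers, np.full(n_blobs, 250.0),
                     np.full(n_blobs, 150.0), psf_sigma_nm=psf)
    fixed = VoxelGrid(channels=["fiducial"], data=F[None], pitch_nm=pitch_nm)

    def rot(a, axis):
        c, s = math.cos(a), math.sin(a)
        m = np.eye(3)
        i, j = [(1, 2), (0, 2), (0, 1)][axis]
        m[i, i] = c; m[j, j] = c; m[i, j] = -s; m[j, i] = s
        return m

    angles = rng.uniform(-math.radians(rotation_deg), math.radians(rotation_deg), 3)
    scales = rng.uniform(*scale_range, size=3)
    linear = rot(angles[0], 0) @ rot(angles[1], 1) @ rot(angles[2], 2) @ np.diag(scales)
    pitch_xyz = np.array([px, py, pz])
    from ..transforms import SinusoidalWarp, resample_through as _rt
    warp = SinusoidalWarp(
        linear=linear,
        translation_nm=rng.uniform(-1, 1, 3) * translation_vox * pitch_xyz,
        center_nm=ext / 2,
        amplitude_nm=wobble_vox * pitch_xyz,
        period_nm=ext / rng.uniform(1.0, 2.0, 3),
        phase=rng.uniform(0, 2 * math.pi, 3),
    )
    moving = _rt(fixed, warp)
    if noise is not None and noise.enabled:
        fixed.data = apply_noise(fixed.data, noise, rng)
        moving.data = apply_noise(moving.data, noise, rng)
    moving.round_id = 2
    return fixed, moving, centers, warp


def generate_expansion_pair(factor: float, seed: int | np.random.Generator,
                            shape=(64, 160, 160), pitch_nm=(200.0, 75.0, 75.0),
                            n_blobs: int = 4000,
                            noise: "NoiseConfig | None" = None):
    """The same blob structure imaged at two expansion states.

    The post-expansion grid keeps the voxel pitch but the structure is
    ``factor`` times larger, so only the central ``1/factor`` of the
    pre-expansion content remains in the field of view — exactly the
    situation the expansion-factor measurement faces.
    Returns ``(pre_grid, post_grid)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nz, ny, nx = shape
    pz, py, px = pitch_nm
    ext = np.array([(nx - 1) * px, (ny - 1) * py, (nz - 1) * pz])
    centers = np.stack([rng.uniform(300, e - 300, n_blobs) for e in ext], axis=1)
    psf = tuple(p / 2.3548 for p in pitch_nm)
    F = render_blobs(shape, pitch_nm, centers, np.full(n_blobs, 150.0),
                     np.full(n_blobs, 150.0), psf_sigma_nm=psf)
    c = ext / 2
    post_centers = c + factor * (centers - c)
    keep = np.all((post_centers > 300) & (post_centers < ext - 300), axis=1)
    P = render_blobs(shape, pitch_nm, post_centers[keep],
                     np.full(int(keep.sum()), 150.0 * factor),
                     np.full(int(keep.sum()), 150.0), psf_sigma_nm=psf)
    pre = VoxelGrid(channels=["structure"], data=F[None], pitch_nm=pitch_nm)
    post = VoxelGrid(channels=["structure"], data=P[None], pitch_nm=pitch_nm)
    if noise is not None and noise.enabled:
        pre.data = apply_noise(pre.data, noise, rng)
        post.data = apply_noise(post.data, noise, rng)
    return pre, post


def generate_puncta_field(config: SceneConfig, n_bassoon: int,
                          seed: int | np.random.Generator):
    """A neurite-free field of Bassoon/PSD pairs with the configured mixture.

    Used to study pairing in isolation.  Returns ``(grid, composition)``
    where composition maps {"excitatory", "inhibitory", "orphan"} to planted
    counts.  Positions respect the >=300 nm spacing rule.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sx, sy, sz = config.size_nm
    positions: list[np.ndarray] = []
    tries = 0
    while len(positions) < n_bassoon and tries < 200 * n_bassoon:
        tries += 1
        p = np.array([rng.uniform(1000, sx - 1000), rng.uniform(1000, sy - 1000),
                      rng.uniform(1000, sz - 1000)])
        if not positions or np.min(
                np.linalg.norm(np.array(positions) - p, axis=1)) >= config.min_spacing_nm:
            positions.append(p)
    if len(positions) < n_bassoon:
        raise SceneError(f"could not place {n_bassoon} puncta with spacing "
                         f"{config.min_spacing_nm} nm in this volume")
    kinds = rng.choice(3, size=n_bassoon, p=list(config.mixture))
    seps = _truncnorm(rng, config.separation_mean_nm, config.separation_sd_nm,
                      *config.separation_range_nm, size=n_bassoon)
    vols = rng.uniform(*config.psd_volume_um3, size=n_bassoon)
    entries = []
    for i, p in enumerate(positions):
        normal = rng.normal(size=3)
        normal /= np.linalg.norm(normal)
        entries.append(("Bassoon", p + seps[i] * normal, BASSOON_SIGMA_NM))
        if kinds[i] == 0:
            entries.append(("Homer1", p, _psd_sigma_nm(vols[i])))
        elif kinds[i] == 1:
            entries.append(("Gephyrin", p, _psd_sigma_nm(vols[i])))
    shape = config.grid_shape
    data = np.zeros((3,) + shape, dtype=np.float32)
    for ci, ch in enumerate(PUNCTA_CHANNELS):
        sel = [e for e in entries if e[0] == ch]
        if sel:
            data[ci] = render_blobs(shape, config.pitch_nm,
                                    np.array([e[1] for e in sel]),
                                    np.array([e[2] for e in sel]),
                                    np.full(len(sel), config.puncta_amplitude),
                                    psf_sigma_nm=config.psf_sigma_nm)
    grid = VoxelGrid(channels=list(PUNCTA_CHANNELS), data=data,
                     pitch_nm=config.pitch_nm,
                     expansion_factor=config.expansion_factor)
    if config.noise.enabled:
        grid.data = apply_noise(grid.data, config.noise, rng)
    composition = {
        "excitatory": int(np.sum(kinds == 0)),
        "inhibitory": int(np.sum(kinds == 1)),
        "orphan": int(np.sum(kinds == 2)),
    }
    return grid, composition
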