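"""Domain types shared across the pipeline.

Conventions
-----------
* Voxel data are indexed ``(channel, z, y, x)``; voxel pitch is stored as
  ``(z, y, x)`` in **pre-expansion nanometers**.  A voxel's physical position
  is its center: ``position_nm = index * pitch_nm`` (0-based indices).
* All point coordinates on domain objects (skeleton nodes, synapse records,
  marker peaks) are ``(x, y, z)`` in pre-expansion nanometers, matching the
  SWC axis order.
* Expansion is metadata: measurements are made on the expanded gel but every
  stored length/volume is divided back to tissue scale, so converting to the
  expanded frame and back is the identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "VoxelGrid",
    "SkeletonNode",
    "Skeleton",
    "SynapseRecord",
    "ColorVector",
    "Punctum",
    "MarkerPair",
    "TrioVerdict",
    "LineProfile",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


def _as_tuple3(v) -> tuple[float, float, float]:
    t = tuple(float(x) for x in v)
    if len(t) != 3:
        raise ValidationError(f"expected 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass
class VoxelGrid:
    """A named multichannel 3-D intensity grid.

    Parameters
    ----------
    channels
        Channel names, e.g. ``["FP1", "FP2", "FP3", "Bassoon", "Gephyrin"]``.
    data
        Array of shape ``(n_channels, nz, ny, nx)``, nonnegative intensities.
    pitch_nm
        Per-axis voxel pitch ``(z, y, x)`` in pre-expansion nanometers.
    expansion_factor
        Physical gel magnification (> 1 for expanded samples).  The physical
        gel pitch equals ``pitch_nm * expansion_factor``.
    round_id
        1-based imaging-round identifier.
    """

    channels: list[str]
    data: np.ndarray
    pitch_nm: tuple[float, float, float]
    expansion_factor: float = 1.0
    round_id: int = 1

    def __post_init__(self):
        self.channels = list(self.channels)
        self.pitch_nm = _as_tuple3(self.pitch_nm)
        self.validate()

    def validate(self) -> None:
        if len(self.channels) == 0:
            raise ValidationError("VoxelGrid needs at least one channel")
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError("duplicate channel names")
        if self.data.ndim != 4:
            raise ValidationError(f"data must be 4-D (c,z,y,x), got ndim={self.data.ndim}")
        if self.data.shape[0] != len(self.channels):
            raise ValidationError(
                f"{len(self.channels)} channel names but data has {self.data.shape[0]} channels"
            )
        if any(p <= 0 for p in self.pitch_nm):
            raise ValidationError(f"pitch_nm must be strictly positive, got {self.pitch_nm}")
        if self.expansion_factor <= 0:
            raise ValidationError("expansion_factor must be > 0")
        if self.round_id < 1:
            raise ValidationError("round_id must be >= 1")

    # -- accessors ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial shape (nz, ny, nx)."""
        return self.data.shape[1:]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def voxel_volume_um3(self) -> float:
        pz, py, px = self.pitch_nm
        return pz * py * px * 1e-9

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.channels.index(name)]
        except ValueError:
            raise KeyError(f"channel {name!r} not in {self.channels}") from None

    def has_channel(self, name: str) -> bool:
        return name in self.channels

    # -- coordinate conversions -------------------------------------------
    def xyz_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Physical (x,y,z) nm -> fractional (z,y,x) voxel indices."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        pz, py, px = self.pitch_nm
        idx = np.stack([xyz[:, 2] / pz, xyz[:, 1] / py, xyz[:, 0] / px], axis=1)
        return idx

    def index_to_xyz(self, zyx: np.ndarray) -> np.ndarray:
        """Fractional (z,y,x) voxel indices -> physical (x,y,z) nm."""
        zyx = np.atleast_2d(np.asarray(zyx, dtype=float))
        pz, py, px = self.pitch_nm
        return np.stack([zyx[:, 2] * px, zyx[:, 1] * py, zyx[:, 0] * pz], axis=1)

    def extent_nm(self) -> tuple[float, float, float]:
        """Physical size (x, y, z) spanned by voxel centers."""
        nz, ny, nx = self.shape
        pz, py, px = self.pitch_nm
        return ((nx - 1) * px, (ny - 1) * py, (nz - 1) * pz)

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(
            channels=list(self.channels),
            data=self.data.copy(),
            pitch_nm=self.pitch_nm,
            expansion_factor=self.expansion_factor,
            round_id=self.round_id,
        )


# SWC structure type codes
SWC_SOMA = 1
SWC_AXON = 2
SWC_DENDRITE = 3


@dataclass
class SkeletonNode:
    node_id: int
    swc_type: int
    position: tuple[float, float, float]  # (x, y, z) pre-expansion nm
    radius: float  # nm
    parent_id: int  # -1 for root
    synapse_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.radius < 0:
            raise ValidationError(f"node {self.node_id}: radius must be >= 0")
        self.position = _as_tuple3(self.position)


@dataclass
class Skeleton:
    """One connected SWC tree (a neuron, or an axon fragment without soma)."""

    neuron_id: str
    nodes: list[SkeletonNode]
    label: str = ""
    color: Optional["ColorVector"] = None

    def __post_init__(self):
        self._index = {n.node_id: n for n in self.nodes}
        if len(self._index) != len(self.nodes):
            raise ValidationError(f"skeleton {self.neuron_id}: duplicate node ids")
        self.validate()

    def validate(self) -> None:
        roots = 0
        for n in self.nodes:
            if n.parent_id == -1:
                roots += 1
            elif n.parent_id not in self._index:
                raise ValidationError(
                    f"skeleton {self.neuron_id}: node {n.node_id} has dangling parent {n.parent_id}"
                )
        if self.nodes and roots != 1:
            raise ValidationError(
                f"skeleton {self.neuron_id}: expected exactly one root, found {roots}"
            )
        # cycle check: every node must reach the root
        seen_ok: set[int] = set()
        for n in self.nodes:
            trail = []
            cur = n
            while cur.node_id not in seen_ok and cur.parent_id != -1:
                trail.append(cur.node_id)
                if cur.parent_id in trail:
                    raise ValidationError(f"skeleton {self.neuron_id}: cyclic parent links")
                cur = self._index[cur.parent_id]
            seen_ok.update(trail)
            seen_ok.add(cur.node_id)

    def node(self, node_id: int) -> SkeletonNode:
        return self._index[node_id]

    @property
    def root(self) -> SkeletonNode:
        return next(n for n in self.nodes if n.parent_id == -1)

    def positions(self, swc_types: Optional[Sequence[int]] = None) -> np.ndarray:
        """(n, 3) array of (x,y,z) positions, optionally filtered by type."""
        nodes = self.nodes if swc_types is None else [
            n for n in self.nodes if n.swc_type in swc_types
        ]
        if not nodes:
            return np.empty((0, 3))
        return np.array([n.position for n in nodes], dtype=float)

    def nodes_of_type(self, *swc_types: int) -> list[SkeletonNode]:
        return [n for n in self.nodes if n.swc_type in swc_types]

    def children_map(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {n.node_id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent_id != -1:
                ch[n.parent_id].append(n.node_id)
        return ch

    def edges(self) -> list[tuple[SkeletonNode, SkeletonNode]]:
        """(parent, child) pairs."""
        return [
            (self._index[n.parent_id], n) for n in self.nodes if n.parent_id != -1
        ]

    @property
    def has_soma(self) -> bool:
        return any(n.swc_type == SWC_SOMA for n in self.nodes)


@dataclass
class ColorVector:
    """Mean fluorescent-protein intensities and their ternary (simplex) projection."""

    raw: tuple[float, float, float]

    def __post_init__(self):
        self.raw = _as_tuple3(self.raw)
        if any(v < 0 for v in self.raw):
            raise ValidationError(f"raw color components must be nonnegative: {self.raw}")

    @property
    def simplex(self) -> tuple[float, float, float]:
        s = sum(self.raw)
        if s <= 0:
            raise ValidationError("undefined color: raw intensities sum to zero")
        return tuple(v / s for v in self.raw)  # type: ignore[return-value]

    @property
    def defined(self) -> bool:
        return sum(self.raw) > 0

    def distance(self, other: "ColorVector") -> float:
        a, b = self.simplex, other.simplex
        return math.dist(a, b)


@dataclass
class SynapseRecord:
    """One putative synapse, linked to its pre and post structures."""

    synapse_id: str
    kind: str  # "inhibitory" | "excitatory"
    position: tuple[float, float, float]  # (x,y,z) pre-expansion nm
    post_neuron_id: str
    pre_axon_id: str = "unlabeled"
    gephyrin_or_homer_peak: Optional[tuple[float, float, float]] = None
    bassoon_peak: Optional[tuple[float, float, float]] = None
    peak_separation_nm: Optional[float] = None
    compartment: str = "dendritic"  # "somatic" | "dendritic"
    psd_volume_um3: Optional[float] = None
    node_id: Optional[int] = None

    def __post_init__(self):
        if self.kind not in ("inhibitory", "excitatory"):
            raise ValidationError(f"kind must be inhibitory|excitatory, got {self.kind!r}")
        if self.compartment not in ("somatic", "dendritic"):
            raise ValidationError(f"bad compartment {self.compartment!r}")
        self.position = _as_tuple3(self.position)
        if self.gephyrin_or_homer_peak is not None and self.bassoon_peak is not None:
            d = math.dist(self.gephyrin_or_homer_peak, self.bassoon_peak)
            if self.peak_separation_nm is None:
                self.peak_separation_nm = d
            elif not math.isclose(d, self.peak_separation_nm, rel_tol=1e-6, abs_tol=1e-6):
                raise ValidationError(
                    f"peak_separation_nm={self.peak_separation_nm} inconsistent with peaks (distance {d})"
                )


# ---------------------------------------------------------------------------
# Detection-side types
# ---------------------------------------------------------------------------

@dataclass
class Punctum:
    """A segmented synaptic-marker blob."""

    punctum_id: int
    channel: str  # Bassoon | Gephyrin | Homer1
    centroid: tuple[float, float, float]  # (x,y,z) pre-expansion nm
    volume_um3: float  # pre-expansion
    peak_intensity: float
    voxel_count: int

    def __post_init__(self):
        self.centroid = _as_tuple3(self.centroid)


@dataclass
class MarkerPair:
    """A matched presynaptic (Bassoon) / postsynaptic (Gephyrin or Homer1) pair."""

    pre: Punctum
    post: Punctum
    separation_nm: float
    exclusivity_resolved: bool = True

    @property
    def kind(self) -> str:
        return "inhibitory" if self.post.channel == "Gephyrin" else "excitatory"


@dataclass
class LineProfile:
    """Per-channel intensity sampled along a straight segment.

    ``positions_nm`` are signed distances along the axis from the first sample;
    ``normalized`` maps each channel independently to [0, 1] (flat channels map
    to all-zeros).
    """

    positions_nm: np.ndarray
    raw: dict[str, np.ndarray]
    normalized: dict[str, np.ndarray]
    p0: tuple[float, float, float]
    p1: tuple[float, float, float]


REJECT_REASONS = (
    "accepted",
    "no-machinery",
    "order-violation",
    "separation-out-of-range",
    "post-membrane-absent",
    "unlabeled-partner",
)


@dataclass
class TrioVerdict:
    """Outcome of the trio (PSD - postsynaptic membrane - Bassoon) test."""

    pair: MarkerPair
    accepted: bool
    reason: str
    profile: Optional[LineProfile] = None
    psd_peak_nm: Optional[float] = None       # along-profile positions
    bassoon_peak_nm: Optional[float] = None
    membrane_peak_nm: Optional[float] = None
    separation_nm: Optional[float] = None     # measured from profile peaks
    post_neuron_id: Optional[str] = None
    pre_axon_id: Optional[str] = None         # None => unlabeled

    def __post_init__(self):
        if self.reason not in REJECT_REASONS:
            raise ValidationError(f"unknown verdict reason {self.reason!r}")
        if self.accepted != (self.reason == "accepted"):
            raise ValidationError("accepted flag inconsistent with reason")
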