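"""File I/O: multipage TIFF volumes with JSON sidecars, SWC forests with a
synapse-annotation column, and synapse coordinate tables.

On-disk conventions
-------------------
* Volumes: multipage TIFF with pages ordered ``(channel, z)`` (channel-major),
  plus ``<stem>.json`` holding channels, pitch, expansion factor, round id and
  the storage encoding.  Integer-valued data within uint16 range are stored as
  uint16 (with a scale factor, normally 1.0); anything else as float32.  Both
  branches round-trip exactly.
* SWC: whitespace-delimited, ``#`` comments, 7 standard columns and an
  optional 8th column carrying a semicolon-delimited list of synapse ids
  ("0" when the node carries none).
* Synapse CSV header:
  ``id,x_nm,y_nm,z_nm,kind,pre_axon,post_neuron,compartment,psd_volume_um3``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .types import Skeleton, SkeletonNode, SynapseRecord, ValidationError, VoxelGrid

__all__ = [
    "read_volume",
    "write_volume",
    "read_swc",
    "write_swc",
    "read_synapse_csv",
    "write_synapse_csv",
    "FormatError",
]

SYNAPSE_CSV_COLUMNS = [
    "id", "x_nm", "y_nm", "z_nm", "kind", "pre_axon", "post_neuron",
    "compartment", "psd_volume_um3",
]


class FormatError(ValueError):
    """Raised when an on-disk file does not match its declared layout."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_volume(grid: VoxelGrid, path) -> Path:
    """Write ``grid`` as a multipage TIFF plus JSON sidecar.

    ``read_volume`` inverts this exactly.  NaNs are forbidden on disk.
    """
    path = Path(path)
    grid.validate()
    data = np.asarray(grid.data)
    if np.isnan(data).any():
        raise ValidationError("volume contains NaN; refusing to write")
    if data.min() < 0:
        raise ValidationError("volume contains negative intensities; refusing to write")

    integral = (
        data.size == 0
        or (np.all(data == np.floor(data)) and data.max(initial=0) <= 65535)
    )
    if integral:
        stored = data.astype(np.uint16)
        encoding = {"dtype": "uint16", "scale": 1.0}
    else:
        stored = data.astype(np.float32)
        if not np.allclose(stored.astype(float), data, rtol=0, atol=0, equal_nan=False):
            # keep float64 payloads that do not fit float32 exactly
            stored = data.astype(np.float64)
            encoding = {"dtype": "float64", "scale": 1.0}
        else:
            encoding = {"dtype": "float32", "scale": 1.0}

    c, z, y, x = stored.shape
    tifffile.imwrite(path, stored.reshape(c * z, y, x),
                     photometric="minisblack")
    meta = {
        "channels": grid.channels,
        "pitch_nm": list(grid.pitch_nm),
        "expansion_factor": grid.expansion_factor,
        "round_id": grid.round_id,
        "n_channels": c,
        "n_z": z,
        "encoding": encoding,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_volume(path, metadata: Optional[dict] = None) -> VoxelGrid:
    """Read a multipage TIFF into a :class:`VoxelGrid`.

    ``metadata`` overrides/replaces the JSON sidecar; it must supply
    ``channels`` and ``pitch_nm`` and may supply ``expansion_factor`` and
    ``round_id``.  Intensities are widened to floating point.
    """
    path = Path(path)
    if metadata is None:
        sc = _sidecar_path(path)
        if not sc.exists():
            raise FormatError(f"no metadata sidecar found at {sc}")
        metadata = json.loads(sc.read_text())
    channels = metadata["channels"]
    pitch = metadata["pitch_nm"]
    if any(p <= 0 for p in pitch):
        raise ValidationError(f"nonpositive pitch in metadata: {pitch}")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    n_pages = pages.shape[0]
    n_ch = len(channels)
    if n_ch == 0 or n_pages % n_ch != 0:
        raise FormatError(
            f"{n_pages} TIFF pages not divisible by {n_ch} declared channels"
        )
    nz = n_pages // n_ch
    scale = float(metadata.get("encoding", {}).get("scale", 1.0))
    data = pages.reshape(n_ch, nz, pages.shape[1], pages.shape[2]).astype(np.float64)
    if scale != 1.0:
        data *= scale
    return VoxelGrid(
        channels=list(channels),
        data=data,
        pitch_nm=tuple(pitch),
        expansion_factor=float(metadata.get("expansion_factor", 1.0)),
        round_id=int(metadata.get("round_id", 1)),
    )


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------

def read_swc(path) -> list[Skeleton]:
    """Parse a (possibly multi-tree) SWC file into one Skeleton per root.

    Accepts 7-column standard SWC or the 8-column variant whose last column is
    a semicolon-delimited synapse-id list ("0" = none).  Neuron ids are taken
    from ``# neuron_id:`` comment blocks when present, else synthesized as
    ``<stem>_<k>``.
    """
    path = Path(path)
    nodes: dict[int, SkeletonNode] = {}
    id_labels: dict[int, tuple[str, str]] = {}  # root node -> (neuron_id, label)
    pending_meta: Optional[tuple[str, str]] = None
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("neuron_id:"):
                rest = body[len("neuron_id:"):].strip().split("\t")
                nid = rest[0].strip()
                label = rest[1].strip() if len(rest) > 1 else ""
                pending_meta = (nid, label)
            continue
        parts = line.split()
        if len(parts) not in (7, 8):
            raise FormatError(f"{path}:{lineno}: expected 7 or 8 columns, got {len(parts)}")
        nid = int(parts[0])
        if nid in nodes:
            raise FormatError(f"{path}:{lineno}: duplicate node id {nid}")
        syn: list[str] = []
        if len(parts) == 8 and parts[7] != "0":
            syn = parts[7].split(";")
        node = SkeletonNode(
            node_id=nid,
            swc_type=int(parts[1]),
            position=(float(parts[2]), float(parts[3]), float(parts[4])),
            radius=float(parts[5]),
            parent_id=int(parts[6]),
            synapse_ids=syn,
        )
        nodes[nid] = node
        if node.parent_id == -1 and pending_meta is not None:
            id_labels[nid] = pending_meta
            pending_meta = None

    # split the forest into trees
    for n in nodes.values():
        if n.parent_id != -1 and n.parent_id not in nodes:
            raise FormatError(f"{path}: node {n.node_id} references absent parent {n.parent_id}")

    root_of: dict[int, int] = {}

    def find_root(nid: int) -> int:
        trail: list[int] = []
        cur = nid
        while cur not in root_of:
            if cur in trail:
                raise FormatError(f"{path}: cyclic parent links at node {cur}")
            trail.append(cur)
            parent = nodes[cur].parent_id
            if parent == -1:
                root_of[cur] = cur
                break
            cur = parent
        r = root_of[cur]
        for t in trail:
            root_of[t] = r
        return r

    for nid in nodes:
        find_root(nid)

    trees: dict[int, list[SkeletonNode]] = {}
    for nid, n in nodes.items():
        trees.setdefault(root_of[nid], []).append(n)

    skeletons = []
    for k, (root, members) in enumerate(sorted(trees.items())):
        members.sort(key=lambda n: n.node_id)
        neuron_id, label = id_labels.get(root, (f"{path.stem}_{k}", ""))
        skeletons.append(Skeleton(neuron_id=neuron_id, nodes=members, label=label))
    return skeletons


def write_swc(
    skeletons: Sequence[Skeleton],
    synapses: Sequence[SynapseRecord],
    path,
    csv_path=None,
) -> Path:
    """Write skeletons as 8-column SWC and the synapse table as CSV alongside.

    Synapse ids land in column 8 of the node each record is linked to
    (``record.node_id``); nodes without synapses carry "0".  Every record's
    ``post_neuron_id`` must name one of ``skeletons``.
    """
    path = Path(path)
    known = {s.neuron_id for s in skeletons}
    for rec in synapses:
        if rec.post_neuron_id not in known:
            raise ValidationError(
                f"synapse {rec.synapse_id} references unknown neuron {rec.post_neuron_id!r}"
            )
    by_node: dict[tuple[str, int], list[str]] = {}
    for rec in synapses:
        if rec.node_id is not None:
            by_node.setdefault((rec.post_neuron_id, rec.node_id), []).append(rec.synapse_id)

    lines = ["# id type x y z radius parent synapse_ids"]
    for sk in skeletons:
        label = sk.label or ""
        lines.append(f"# neuron_id: {sk.neuron_id}\t{label}")
        for n in sk.nodes:
            syn = by_node.get((sk.neuron_id, n.node_id)) or n.synapse_ids
            col8 = ";".join(syn) if syn else "0"
            x, y, z = n.position
            lines.append(
                f"{n.node_id} {n.swc_type} {x:.3f} {y:.3f} {z:.3f} {n.radius:.3f} {n.parent_id} {col8}"
            )
    path.write_text("\n".join(lines) + "\n")
    write_synapse_csv(synapses, csv_path or path.with_suffix(".csv"))
    return path


# ---------------------------------------------------------------------------
# Synapse CSV
# ---------------------------------------------------------------------------

def write_synapse_csv(synapses: Iterable[SynapseRecord], path) -> Path:
    path = Path(path)
    rows = []
    for r in synapses:
        rows.append({
            "id": r.synapse_id,
            "x_nm": r.position[0],
            "y_nm": r.position[1],
            "z_nm": r.position[2],
            "kind": r.kind,
            "pre_axon": r.pre_axon_id,
            "post_neuron": r.post_neuron_id,
            "compartment": r.compartment,
            "psd_volume_um3": r.psd_volume_um3,
        })
    df = pd.DataFrame(rows, columns=SYNAPSE_CSV_COLUMNS)
    df.to_csv(path, index=False)
    return path


def read_synapse_csv(path) -> list[SynapseRecord]:
    df = pd.read_csv(path, dtype={"id": str, "pre_axon": str, "post_neuron": str})
    missing = [c for c in SYNAPSE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"synapse CSV missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        vol = row["psd_volume_um3"]
        out.append(SynapseRecord(
            synapse_id=str(row["id"]),
            kind=str(row["kind"]),
            position=(float(row["x_nm"]), float(row["y_nm"]), float(row["z_nm"])),
            pre_axon_id=str(row["pre_axon"]),
            post_neuron_id=str(row["post_neuron"]),
            compartment=str(row["compartment"]),
            psd_volume_um3=None if pd.isna(vol) else float(vol),
        ))
    return out
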