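"""Scene configuration and ground-truth containers for the synthetic generator.

The generator emulates the study conditions: membrane-targeted three-FP
Brainbow labeling of interneuron somata/dendrites and passing axons, planted
Gephyrin/Homer1-Bassoon machinery at axon-membrane appositions (peak
separation ~150 nm, range 100-200 nm), two distractor classes (contacts
without machinery; labeled axons passing a synapse that belongs to an
unlabeled partner), mostly >300 nm inter-synapse spacing, and multi-round
imaging with misalignment and multiplicative signal decay.  All lengths are
pre-expansion nanometers unless a name says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from ..types import Skeleton, SynapseRecord

__all__ = ["NoiseConfig", "SceneConfig", "GroundTruth"]


@dataclass
class NoiseConfig:
    """Photon-counting noise: Poisson shot noise on (signal + background)
    plus Gaussian read noise, rounded to integer counts."""

    enabled: bool = True
    background_mean: float = 3.0   # counts
    read_sigma: float = 1.5        # counts


@dataclass
class SceneConfig:
    # volume geometry (pre-expansion)
    size_um: tuple[float, float, float] = (46.0, 46.0, 18.0)  # (x, y, z)
    pitch_nm: tuple[float, float, float] = (200.0, 75.0, 75.0)  # (z, y, x)
    expansion_factor: float = 4.0

    # structures
    n_neurons: int = 8
    n_external_axons: int = 30
    soma_radius_um: tuple[float, float] = (5.0, 6.0)
    dendrite_radius_nm: float = 500.0
    axon_radius_nm: float = 300.0
    membrane_thickness_nm: float = 40.0
    node_spacing_nm: float = 37.5          # <= half the smallest pitch
    n_stems: tuple[int, int] = (4, 6)      # dendritic stems per neuron (inclusive range)
    dendrite_total_um: float = 350.0       # target dendritic length per neuron
    branch_prob_per_um: float = 0.06
    contacts_per_axon: int = 7             # intended close appositions per external axon
    contacts_per_neuron_axon: int = 3
    near_miss_per_axon: int = 1            # passes at ~700 nm for unlabeled-partner distractors

    # colors (ternary simplex)
    n_color_clusters: int = 10
    color_min_separation: float = 0.15
    color_jitter: float = 0.02

    # synapse planting
    n_synapses: int = 150
    mixture: tuple[float, float, float] = (0.77, 0.21, 0.02)  # excit pair, inhib pair, orphan Bassoon
    separation_mean_nm: float = 150.0
    separation_sd_nm: float = 25.0
    separation_range_nm: tuple[float, float] = (100.0, 200.0)
    min_spacing_nm: float = 310.0
    close_fraction: float = 0.025          # fraction planted 180-290 nm from a sibling
                                           # (each close planting leaves two synapses
                                           # under 300 nm, so ~5% fall below threshold)
    somatic_fraction: float = 0.4
    n_distractor_contact: int = 15
    n_distractor_unlabeled: int = 15
    psd_volume_um3: tuple[float, float] = (0.015, 0.05)
    cleft_nm: float = 20.0

    # optics / intensities (counts)
    psf_fwhm_nm: Optional[tuple[float, float, float]] = None  # (z,y,x); None -> pitch
    fp_amplitude: float = 12.0             # counts per membrane surface sample
    puncta_amplitude: float = 180.0        # blob peak
    fiducial_n_blobs: int = 400
    fiducial_sigma_nm: float = 250.0   # >= z pitch: fiducials must be z-resolvable
    fiducial_amplitude: float = 150.0

    # rounds
    n_rounds: int = 1
    decay: float = 0.83                    # per elution step, stain channels
    decay_fiducial: bool = False           # fiducial is re-stained every round
    round_translation_vox: float = 8.0     # max |translation| per axis, voxels
    round_rotation_deg: float = 2.5
    round_scale_range: tuple[float, float] = (0.98, 1.04)
    round_wobble_vox: float = 1.0          # sinusoidal displacement amplitude

    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0

    # ------------------------------------------------------------------
    def __post_init__(self):
        if isinstance(self.noise, dict):
            self.noise = NoiseConfig(**self.noise)
        if self.expansion_factor <= 1:
            raise ValueError("expansion_factor must be > 1")
        if any(c < 0 for c in (self.n_neurons, self.n_external_axons, self.n_synapses,
                               self.n_distractor_contact, self.n_distractor_unlabeled)):
            raise ValueError("counts must be >= 0")
        if abs(sum(self.mixture) - 1.0) > 1e-9:
            raise ValueError("mixture must sum to 1")

    @property
    def size_nm(self) -> tuple[float, float, float]:
        return tuple(s * 1000.0 for s in self.size_um)  # (x,y,z)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        """(nz, ny, nx) such that voxel centers span the volume."""
        sx, sy, sz = self.size_nm
        pz, py, px = self.pitch_nm
        return (int(round(sz / pz)) + 1, int(round(sy / py)) + 1, int(round(sx / px)) + 1)

    @property
    def psf_fwhm(self) -> tuple[float, float, float]:
        return self.psf_fwhm_nm if self.psf_fwhm_nm is not None else tuple(self.pitch_nm)

    @property
    def psf_sigma_nm(self) -> tuple[float, float, float]:
        return tuple(f / 2.3548200450309493 for f in self.psf_fwhm)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseConfig(**d["noise"])
        for key in ("size_um", "pitch_nm", "soma_radius_um", "n_stems", "mixture",
                    "separation_range_nm", "round_scale_range", "psd_volume_um3",
                    "psf_fwhm_nm"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Everything the generator planted, for parameter-recovery checks."""

    config: SceneConfig
    skeletons: list[Skeleton]
    synapses: list[SynapseRecord]                 # true planted synapses (pairs only)
    orphan_bassoon_xyz: np.ndarray                # (n,3) unpaired Bassoon puncta
    distractors_contact: list[dict]               # contact-no-machinery sites
    distractors_unlabeled: list[SynapseRecord]    # pairs whose true partner is unlabeled
    color_clusters: dict[str, int]                # structure id -> planted cluster index
    cluster_centers: np.ndarray                   # (k, 3) simplex coordinates
    fiducial_centers_xyz: Optional[np.ndarray] = None
    round_warps: list = field(default_factory=list)   # planted warp per round (index 0 = round 1 = identity/None)
    decay: float = 1.0

    @property
    def connectivity(self) -> pd.DataFrame:
        """Planted connectivity matrix: rows = pre axons, cols = post neurons."""
        posts = sorted({s.neuron_id for s in self.skeletons if s.has_soma})
        pres = sorted({r.pre_axon_id for r in self.synapses})
        mat = pd.DataFrame(0, index=pres, columns=posts, dtype=int)
        for r in self.synapses:
            mat.loc[r.pre_axon_id, r.post_neuron_id] += 1
        return mat

    def source_count(self, post_neuron_id: str) -> int:
        """Number of distinct planted pre axons innervating a target."""
        return len({r.pre_axon_id for r in self.synapses if r.post_neuron_id == post_neuron_id})
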