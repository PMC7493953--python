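"""Brainbow color assignment on the ternary simplex.

Each labeled structure carries a 3-component color (relative FP expression)
that lives on the unit simplex.  Cluster centers are sampled with a minimum
pairwise separation (so "spectrally unique" structures are resolvable), and
every structure gets its cluster center plus a small jitter, re-projected to
the simplex.  Fragments of the same source always share one color.
"""

from __future__ import annotations

import numpy as np

from ..types import ColorVector, Skeleton
from .skeletons import SceneError

__all__ = ["sample_simplex_centers", "assign_colors", "jittered_color"]


def _simplex_lattice(spacing: float) -> np.ndarray:
    """Triangular lattice on the simplex with nearest-neighbor L2 ~= spacing."""
    n = int(np.floor(np.sqrt(2.0) / spacing))
    if n < 1:
        return np.array([[1 / 3, 1 / 3, 1 / 3]])
    pts = []
    for i in range(n + 1):
        for j in range(n + 1 - i):
            pts.append((i / n, j / n, (n - i - j) / n))
    return np.array(pts)


def sample_simplex_centers(k: int, min_separation: float,
                           rng: np.random.Generator,
                           max_tries: int = 20000) -> np.ndarray:
    """k points on the unit simplex with pairwise L2 distance >= min_separation.

    Rejection-samples from the uniform (flat Dirichlet) distribution; for
    packings too dense for rejection sampling it falls back to drawing from a
    triangular lattice at the requested spacing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < k and tries < max_tries:
        c = rng.dirichlet(np.ones(3))
        tries += 1
        if all(np.linalg.norm(c - e) >= min_separation for e in centers):
            centers.append(c)
    if len(centers) == k:
        return np.array(centers)
    lattice = _simplex_lattice(min_separation)
    if len(lattice) < k:
        raise SceneError(
            f"cannot pack {k} colors at separation {min_separation} on the simplex"
        )
    pick = rng.choice(len(lattice), size=k, replace=False)
    return lattice[pick]


def jittered_color(center: np.ndarray, jitter: float,
                   rng: np.random.Generator) -> ColorVector:
    """Center + Gaussian jitter, clipped and re-projected to the simplex."""
    c = np.asarray(center, dtype=float) + rng.normal(0.0, jitter, size=3)
    c = np.clip(c, 1e-6, None)
    c = c / c.sum()
    return ColorVector(raw=tuple(c))


def simulate_convergence_target(n_sources: int, rng: np.random.Generator,
                                min_separation: float = 0.15,
                                jitter: float = 0.02,
                                fragments_per_source: tuple[int, int] = (1, 3)):
    """Colors of the axon fragments innervating one synthetic target.

    Each of ``n_sources`` source neurons gets a distinct simplex color
    (pairwise separation >= ``min_separation``) and contributes 1-3 spatially
    distinct fragments, each jittered around the source color.  Returns
    ``(fragment_colors (n,3), fragment_source_index (n,))``.
    """
    centers = sample_simplex_centers(n_sources, min_separation, rng)
    colors, src = [], []
    for i in range(n_sources):
        for _ in range(int(rng.integers(*fragments_per_source, endpoint=True))):
            colors.append(jittered_color(centers[i], jitter, rng).simplex)
            src.append(i)
    return np.array(colors), np.array(src, dtype=int)


def assign_colors(skeletons: list[Skeleton], n_clusters: int,
                  min_separation: float, seed: int | np.random.Generator,
                  jitter: float = 0.02) -> np.ndarray:
    """Assign every skeleton a color drawn from ``n_clusters`` separated
    cluster centers (in place).  Returns the (k, 3) center array; each
    skeleton additionally gets a ``color_cluster`` attribute with its planted
    cluster index.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centers = sample_simplex_centers(n_clusters, min_separation, rng)
    for sk in skeletons:
        ci = int(rng.integers(n_clusters))
        sk.color = jittered_color(centers[ci], jitter, rng)
        sk.color_cluster = ci  # type: ignore[attr-defined]
    return centers
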