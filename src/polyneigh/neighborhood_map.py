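"""Neighbor-probability histograms in the particle reference frame.

For each ribosome the vectors to its n closest neighbors (default n = 4,
neighbors farther than 100 A excluded) are rotated with the inverse of the
ribosome's orientation, giving neighbor coordinates in the frame of the
focal particle (membrane in the xy plane for ER-bound ribosomes).  These
vectors are binned on a regular 3D grid of 15 A voxels and normalized by
the total number of analysed neighbors, yielding the probability of finding
a neighboring particle in each voxel.

The grid is center-registered: voxel edges sit at odd multiples of half the
voxel size, so the focal particle occupies the exact center of the central
voxel and the trailing/leading hemispheres are treated symmetrically.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .particle_io import ParticleTable
from .rigid_geometry import euler_to_rotation_batch

__all__ = [
    "NeighborParams",
    "Neighbor",
    "NeighborSet",
    "HistogramGeometry",
    "ProbabilityHistogram",
    "find_neighbors",
    "accumulate_histogram",
    "project_xy",
    "subgroup_histograms",
]


@dataclasses.dataclass(frozen=True)
class NeighborParams:
    """Neighbor retention rule: up to ``n_neighbors`` within ``max_distance`` A."""

    n_neighbors: int = 4
    max_distance: float = 100.0

    def __post_init__(self):
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")


@dataclasses.dataclass(frozen=True)
class Neighbor:
    """One retained neighbor of a focal particle.

    ``vector`` is the neighbor's position in the focal particle's frame;
    ``vector_rev`` is the focal particle's position in the neighbor's frame
    (needed for the reciprocal polysome-link check, since the neighbor
    relation itself is not symmetric).
    """

    particle_id: int
    vector: np.ndarray
    distance: float
    vector_rev: np.ndarray


@dataclasses.dataclass(frozen=True)
class NeighborSet:
    """Retained neighbors of one focal particle, sorted by distance."""

    tomogram_id: str
    particle_id: int
    neighbors: tuple[Neighbor, ...]


@dataclasses.dataclass(frozen=True)
class HistogramGeometry:
    """Center-registered cubic grid: ``2*half_extent_voxels + 1`` voxels/axis."""

    voxel_size: float = 15.0
    half_extent_voxels: int = 7

    def __post_init__(self):
        if self.voxel_size <= 0 or self.half_extent_voxels < 1:
            raise ValueError("invalid histogram geometry")

    @property
    def n_voxels(self) -> int:
        return 2 * self.half_extent_voxels + 1

    @property
    def shape(self) -> tuple[int, int, int]:
        n = self.n_voxels
        return (n, n, n)

    @property
    def extent(self) -> float:
        """Half-width of the grid in A (edge of the outermost voxel)."""
        return (self.half_extent_voxels + 0.5) * self.voxel_size

    def covers(self, max_distance: float) -> bool:
        """Whether every vector within ``max_distance`` falls inside the grid."""
        return self.voxel_size * self.half_extent_voxels >= max_distance

    def bin_indices(self, vectors: np.ndarray) -> np.ndarray:
        """Map (N, 3) particle-frame vectors to integer voxel indices.

        Raises if any vector falls outside the grid.
        """
        vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
        idx = np.rint(vectors / self.voxel_size).astype(int) + self.half_extent_voxels
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_voxels):
            bad = np.flatnonzero(
                np.any((idx < 0) | (idx >= self.n_voxels), axis=1)
            )[0]
            raise ValueError(
                f"vector {vectors[bad]} outside histogram grid "
                f"(extent +/-{self.extent:g} A)"
            )
        return idx

    def voxel_centers(self) -> np.ndarray:
        """1D array of voxel-center coordinates along one axis (A)."""
        return (
            np.arange(self.n_voxels) - self.half_extent_voxels
        ) * self.voxel_size


@dataclasses.dataclass
class ProbabilityHistogram:
    """3D neighbor-probability histogram for one particle population."""

    geometry: HistogramGeometry
    counts: np.ndarray
    total_neighbors: int
    population_tag: str = ""

    @property
    def probabilities(self) -> np.ndarray:
        if self.total_neighbors == 0:
            return np.zeros(self.geometry.shape)
        return self.counts / float(self.total_neighbors)

    @property
    def is_empty(self) -> bool:
        return self.total_neighbors == 0

    def to_voxel_frame(self) -> pd.DataFrame:
        """Nonzero voxels as a tidy table (x, y, z centers in A, count, probability)."""
        ix, iy, iz = np.nonzero(self.counts)
        c = self.geometry.voxel_centers()
        return pd.DataFrame(
            {
                "x": c[ix],
                "y": c[iy],
                "z": c[iz],
                "count": self.counts[ix, iy, iz],
                "probability": self.probabilities[ix, iy, iz],
            }
        )


def find_neighbors(
    table: ParticleTable, params: NeighborParams = NeighborParams()
) -> list[NeighborSet]:
    """Retained-neighbor sets for every particle in the table.

    The search is restricted to particles sharing the focal particle's
    tomogram and spans all particles regardless of label.  Ties at exactly
    ``max_distance`` are included; ties for the n-th nearest are broken by
    ascending particle_id.  Output order follows table row order.
    """
    if len(table) == 0:
        raise ValueError("particle table is empty")
    out: list[NeighborSet] = []
    for tid, sub in table.per_tomogram():
        pos = sub[["x", "y", "z"]].to_numpy(dtype=float)
        pids = sub["particle_id"].to_numpy(dtype=int)
        rots = euler_to_rotation_batch(sub[["rot", "tilt", "psi"]].to_numpy(float))
        n = len(sub)
        tree = cKDTree(pos) if n > 1 else None
        for i in range(n):
            entries: list[Neighbor] = []
            if tree is not None:
                # small slack so ties at exactly max_distance are kept (<=)
                cand = tree.query_ball_point(
                    pos[i], params.max_distance * (1 + 1e-12)
                )
                cand = [j for j in cand if j != i]
                if cand:
                    d = np.linalg.norm(pos[cand] - pos[i], axis=1)
                    keep = d <= params.max_distance
                    cand = np.asarray(cand)[keep]
                    d = d[keep]
                    order = np.lexsort((pids[cand], d))[: params.n_neighbors]
                    for k in order:
                        j = cand[k]
                        entries.append(
                            Neighbor(
                                particle_id=int(pids[j]),
                                vector=rots[i] @ (pos[j] - pos[i]),
                                distance=float(d[k]),
                                vector_rev=rots[j] @ (pos[i] - pos[j]),
                            )
                        )
            out.append(
                NeighborSet(
                    tomogram_id=tid,
                    particle_id=int(pids[i]),
                    neighbors=tuple(entries),
                )
            )
    return out


def accumulate_histogram(
    neighbor_sets: Iterable[NeighborSet],
    geometry: HistogramGeometry = HistogramGeometry(),
    population_tag: str = "",
) -> ProbabilityHistogram:
    """Bin particle-frame neighbor vectors and normalize to probabilities.

    The normalizer is the total number of retained neighbor vectors across
    all focal particles, so probabilities over the grid sum to 1 whenever
    the geometry covers the search cutoff.
    """
    counts = np.zeros(geometry.shape, dtype=np.int64)
    vectors = [
        nb.vector for ns in neighbor_sets for nb in ns.neighbors
    ]
    total = len(vectors)
    if total:
        idx = geometry.bin_indices(np.asarray(vectors))
        np.add.at(counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1)
    return ProbabilityHistogram(
        geometry=geometry,
        counts=counts,
        total_neighbors=total,
        population_tag=population_tag,
    )


def project_xy(hist: ProbabilityHistogram) -> np.ndarray:
    """Project probabilities onto the xy (membrane) plane by summing over z."""
    return hist.probabilities.sum(axis=2)


def subgroup_histograms(
    table: ParticleTable,
    neighbor_sets: Sequence[NeighborSet],
    geometry: HistogramGeometry = HistogramGeometry(),
    group_by: str = "state_label",
    groups: Sequence[str] | None = None,
) -> dict[str, ProbabilityHistogram]:
    """One histogram per focal-particle group.

    Grouping applies to the focal particle only; retained neighbors are
    whoever is nearby, regardless of their own label.  ``group_by`` is a
    table column (``state_label``, ``population_label``) or the derived
    ``membrane_soluble`` dichotomy (population ``soluble-EBP1`` -> soluble,
    ``unidentified`` excluded, all translocon variants -> membrane).
    """
    labels = _focal_labels(table, group_by)
    key = {(ns.tomogram_id, ns.particle_id): ns for ns in neighbor_sets}
    if groups is None:
        groups = [g for g in dict.fromkeys(labels) if g is not None]
    out = {}
    for g in groups:
        members = [
            key[(row.tomogram_id, int(row.particle_id))]
            for row, lab in zip(table.df.itertuples(index=False), labels)
            if lab == g and (row.tomogram_id, int(row.particle_id)) in key
        ]
        out[g] = accumulate_histogram(members, geometry, population_tag=str(g))
    return out


def _focal_labels(table: ParticleTable, group_by: str) -> list[str | None]:
    if group_by == "membrane_soluble":
        def dichot(pop: str):
            if pop == "soluble-EBP1":
                return "soluble"
            if pop == "unidentified":
                return None
            return "membrane"

        return [dichot(p) for p in table.df["population_label"]]
    if group_by not in ("state_label", "population_label"):
        raise ValueError(f"unsupported group_by {group_by!r}")
    return list(table.df[group_by])
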