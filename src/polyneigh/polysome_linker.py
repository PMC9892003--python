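"""Polysome link detection from trailing/leading neighbor-probability masks.

Supra-threshold clusters of the membrane-bound and soluble neighbor
histograms (thresholds P = 0.0005 and P = 0.0003 respectively) are assigned
to trailing or leading directions, dilated by two voxels, and unioned across
the two populations into one trailing and one leading mask for the whole
dataset.  A trailing-leading connection between two ribosomes is confirmed
reciprocally: the neighbor must fall in the focal particle's trailing
(leading) mask AND the focal particle must fall in the neighbor's leading
(trailing) mask -- the inverse calculation.  Confirmed links are resolved to
at most one upstream and one downstream partner per ribosome (an mRNA
threads a linear chain) and assembled into maximal directed paths.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import ball

from .neighborhood_map import HistogramGeometry, NeighborSet, ProbabilityHistogram
from .particle_io import ParticleTable

__all__ = [
    "MaskParams",
    "DirectionMask",
    "PolysomeEdge",
    "PolysomeLinkSet",
    "build_direction_masks",
    "confirm_links",
    "assemble_chains",
    "per_tomogram_frequencies",
    "AmbiguousClusterError",
]

logger = logging.getLogger(__name__)

TRAILING = "trailing"
LEADING = "leading"


class AmbiguousClusterError(ValueError):
    """A supra-threshold cluster whose direction assignment is ambiguous."""


@dataclasses.dataclass(frozen=True)
class MaskParams:
    """Thresholds and dilation for direction-mask construction.

    ``threshold_membrane`` applies to the membrane-bound population
    histogram, ``threshold_soluble`` to the soluble one; both binary masks
    are dilated by ``dilation_voxels`` (ball structuring element).
    """

    threshold_membrane: float = 0.0005
    threshold_soluble: float = 0.0003
    dilation_voxels: int = 2
    ambiguity_angle_deg: float = 5.0
    #: minimum neighbor vectors supporting a component; guards the small-n
    #: regime where a single count can exceed the probability threshold
    #: (at realistic dataset sizes the threshold alone implies far more)
    min_component_counts: int = 5

    def __post_init__(self):
        for t in (self.threshold_membrane, self.threshold_soluble):
            if not 0.0 < t < 1.0:
                raise ValueError("thresholds must be in (0, 1)")
        if self.dilation_voxels < 0:
            raise ValueError("dilation_voxels must be >= 0")


@dataclasses.dataclass
class DirectionMask:
    """Boolean voxel grid tagging trailing or leading neighbor regions."""

    geometry: HistogramGeometry
    voxels: np.ndarray
    direction: str
    provenance: str = ""

    def contains(self, vectors: np.ndarray) -> np.ndarray:
        """Vectorized membership test; vectors outside the grid are False."""
        vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
        idx = (
            np.rint(vectors / self.geometry.voxel_size).astype(int)
            + self.geometry.half_extent_voxels
        )
        inside = np.all((idx >= 0) & (idx < self.geometry.n_voxels), axis=1)
        out = np.zeros(len(vectors), dtype=bool)
        if inside.any():
            ii = idx[inside]
            out[inside] = self.voxels[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out


@dataclasses.dataclass(frozen=True)
class PolysomeEdge:
    """Directed trailing -> leading association within one tomogram."""

    tomogram_id: str
    trailing_id: int
    leading_id: int
    distance: float


@dataclasses.dataclass
class PolysomeLinkSet:
    """Confirmed polysome links, per-particle membership, and chains."""

    edges: list[PolysomeEdge]
    membership: dict[tuple[str, int], bool]
    chains: list[list[tuple[str, int]]] = dataclasses.field(default_factory=list)

    def n_members(self) -> int:
        return sum(self.membership.values())

    def edges_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.tomogram_id, e.trailing_id, e.leading_id, e.distance) for e in self.edges],
            columns=["tomogram_id", "trailing_id", "leading_id", "distance"],
        )


def _assign_components(
    hist: ProbabilityHistogram,
    threshold: float,
    reference_directions: Mapping[str, np.ndarray],
    ambiguity_angle_deg: float,
    min_component_counts: int = 0,
) -> dict[str, np.ndarray]:
    """Threshold, extract 26-connected components, assign each to a direction.

    Each component goes to the direction whose unit reference vector is
    closest in angle to the component's probability-weighted centroid.
    Components supported by fewer than ``min_component_counts`` neighbor
    vectors are discarded as shot noise.
    """
    prob = hist.probabilities
    binary = prob > threshold
    masks = {d: np.zeros(hist.geometry.shape, dtype=bool) for d in reference_directions}
    if not binary.any():
        return masks
    labeled, n_comp = ndimage.label(binary, structure=np.ones((3, 3, 3), dtype=int))
    centers = hist.geometry.voxel_centers()
    refs = {
        d: np.asarray(v, dtype=float) / np.linalg.norm(v)
        for d, v in reference_directions.items()
    }
    for comp in range(1, n_comp + 1):
        sel = labeled == comp
        if hist.counts[sel].sum() < min_component_counts:
            continue
        w = prob[sel]
        ix, iy, iz = np.nonzero(sel)
        centroid = np.array(
            [np.average(centers[ix], weights=w),
             np.average(centers[iy], weights=w),
             np.average(centers[iz], weights=w)]
        )
        norm = np.linalg.norm(centroid)
        if norm == 0:
            raise AmbiguousClusterError(
                f"component {comp} has zero centroid; cannot assign a direction"
            )
        u = centroid / norm
        angles = {
            d: np.degrees(np.arccos(np.clip(np.dot(u, r), -1.0, 1.0)))
            for d, r in refs.items()
        }
        ranked = sorted(angles.items(), key=lambda kv: kv[1])
        if len(ranked) > 1 and ranked[1][1] - ranked[0][1] < ambiguity_angle_deg:
            raise AmbiguousClusterError(
                f"component {comp} (centroid {centroid.round(1)} A) is ambiguous: "
                f"angles {dict((d, round(a, 2)) for d, a in ranked)}"
            )
        masks[ranked[0][0]] |= sel
    return masks


def build_direction_masks(
    hist_membrane: ProbabilityHistogram,
    hist_soluble: ProbabilityHistogram,
    params: MaskParams = MaskParams(),
    reference_directions: Mapping[str, np.ndarray] | None = None,
) -> tuple[DirectionMask, DirectionMask]:
    """Trailing and leading masks for the whole dataset.

    Per population: threshold the histogram, split supra-threshold voxels
    into 26-connected components, assign components to the direction whose
    reference vector best matches the component centroid, dilate each
    directional mask, then union the membrane-bound and soluble masks per
    direction.

    ``reference_directions`` maps ``"trailing"``/``"leading"`` to unit
    vectors in the particle frame (mRNA entrance/exit sides); it must be
    supplied explicitly -- for synthetic scenes, the planted offsets.
    """
    if reference_directions is None:
        raise ValueError(
            "reference_directions is required (trailing/leading unit vectors "
            "in the particle frame)"
        )
    if hist_membrane.geometry != hist_soluble.geometry:
        raise ValueError("membrane and soluble histograms must share geometry")
    geometry = hist_membrane.geometry
    struct = ball(params.dilation_voxels) if params.dilation_voxels else None

    combined = {d: np.zeros(geometry.shape, dtype=bool) for d in (TRAILING, LEADING)}
    for hist, thr, tag in (
        (hist_membrane, params.threshold_membrane, "membrane"),
        (hist_soluble, params.threshold_soluble, "soluble"),
    ):
        masks = _assign_components(
            hist, thr, reference_directions, params.ambiguity_angle_deg,
            params.min_component_counts,
        )
        if not any(m.any() for m in masks.values()):
            warnings.warn(
                f"no voxel above threshold {thr} in {tag} histogram; empty mask",
                stacklevel=2,
            )
        for d, m in masks.items():
            if struct is not None and m.any():
                m = ndimage.binary_dilation(m, structure=struct)
            combined[d] |= m

    prov = (
        f"membrane>{params.threshold_membrane}, soluble>{params.threshold_soluble}, "
        f"dilated {params.dilation_voxels} voxels"
    )
    return (
        DirectionMask(geometry, combined[TRAILING], TRAILING, prov),
        DirectionMask(geometry, combined[LEADING], LEADING, prov),
    )


def confirm_links(
    neighbor_sets: Sequence[NeighborSet],
    trailing_mask: DirectionMask,
    leading_mask: DirectionMask,
) -> PolysomeLinkSet:
    """Reciprocally confirmed trailing -> leading edges.

    Neighbor j is a confirmed trailing neighbor of focal i iff the vector
    i->j (in i's frame) falls in the trailing mask AND the vector j->i (in
    j's frame) falls in the leading mask; this emits the candidate edge
    j -> i.  Candidates are resolved to at most one in- and one out-edge
    per particle by greedy nearest-first matching (ties broken by particle
    ids), which is independent of focal iteration order.
    """
    candidates: dict[tuple[str, int, int], float] = {}
    for ns in neighbor_sets:
        for nb in ns.neighbors:
            fwd_trail = trailing_mask.contains(nb.vector)[0]
            rev_lead = leading_mask.contains(nb.vector_rev)[0]
            if fwd_trail and rev_lead:
                key = (ns.tomogram_id, nb.particle_id, ns.particle_id)
                candidates.setdefault(key, nb.distance)
            # the symmetric (leading) test emits the opposite edge; it is
            # needed because the neighbor relation is not symmetric
            fwd_lead = leading_mask.contains(nb.vector)[0]
            rev_trail = trailing_mask.contains(nb.vector_rev)[0]
            if fwd_lead and rev_trail:
                key = (ns.tomogram_id, ns.particle_id, nb.particle_id)
                candidates.setdefault(key, nb.distance)

    ranked = sorted(
        candidates.items(), key=lambda kv: (kv[1], kv[0][0], kv[0][1], kv[0][2])
    )
    has_out: set[tuple[str, int]] = set()
    has_in: set[tuple[str, int]] = set()
    edges: list[PolysomeEdge] = []
    for (tid, src, dst), dist in ranked:
        if (tid, src) in has_out or (tid, dst) in has_in:
            continue
        has_out.add((tid, src))
        has_in.add((tid, dst))
        edges.append(PolysomeEdge(tid, src, dst, dist))

    membership = {
        (ns.tomogram_id, ns.particle_id): False for ns in neighbor_sets
    }
    for e in edges:
        membership[(e.tomogram_id, e.trailing_id)] = True
        membership[(e.tomogram_id, e.leading_id)] = True
    return PolysomeLinkSet(edges=edges, membership=membership)


def assemble_chains(links: PolysomeLinkSet) -> PolysomeLinkSet:
    """Populate maximal directed paths; cycles are broken at the longest edge.

    Closed paths can occur on vesicle geodesics; each cycle is opened at its
    largest inter-particle distance and logged.
    """
    out_edge: dict[tuple[str, int], PolysomeEdge] = {}
    in_edge: dict[tuple[str, int], PolysomeEdge] = {}
    for e in links.edges:
        src, dst = (e.tomogram_id, e.trailing_id), (e.tomogram_id, e.leading_id)
        if src in out_edge or dst in in_edge:
            raise RuntimeError("edge multiplicity invariant violated")
        out_edge[src] = e
        in_edge[dst] = e

    edges = list(links.edges)
    # detect cycles: nodes with both in and out, not reachable from a start
    starts = [n for n in out_edge if n not in in_edge]
    visited: set[tuple[str, int]] = set()
    chains: list[list[tuple[str, int]]] = []

    def walk(start: tuple[str, int]) -> list[tuple[str, int]]:
        chain = [start]
        visited.add(start)
        node = start
        while node in out_edge:
            e = out_edge[node]
            node = (e.tomogram_id, e.leading_id)
            if node in visited:
                break
            chain.append(node)
            visited.add(node)
        return chain

    for s in starts:
        chains.append(walk(s))
    # remaining unvisited linked nodes are on cycles
    cyclic = [n for n in out_edge if n not in visited]
    removed: set[tuple[str, int, int]] = set()
    while cyclic:
        node = cyclic[0]
        cycle_nodes = [node]
        cur = node
        while True:
            e = out_edge[cur]
            cur = (e.tomogram_id, e.leading_id)
            if cur == node:
                break
            cycle_nodes.append(cur)
        cycle_edges = [out_edge[n] for n in cycle_nodes]
        worst = max(
            cycle_edges, key=lambda e: (e.distance, e.trailing_id, e.leading_id)
        )
        logger.warning(
            "breaking polysome cycle of length %d in tomogram %s at edge "
            "%d->%d (%.1f A)",
            len(cycle_nodes), worst.tomogram_id, worst.trailing_id,
            worst.leading_id, worst.distance,
        )
        removed.add((worst.tomogram_id, worst.trailing_id, worst.leading_id))
        del out_edge[(worst.tomogram_id, worst.trailing_id)]
        chains.append(walk((worst.tomogram_id, worst.leading_id)))
        cyclic = [n for n in out_edge if n not in visited]

    edges = [
        e for e in edges
        if (e.tomogram_id, e.trailing_id, e.leading_id) not in removed
    ]
    membership = dict(links.membership)
    # breaking a cycle never isolates a particle (cycle length >= 2 leaves a path)
    return PolysomeLinkSet(edges=edges, membership=membership, chains=chains)


def per_tomogram_frequencies(
    table: ParticleTable,
    links: PolysomeLinkSet,
    group_by: str = "state_label",
) -> pd.DataFrame:
    """Per-tomogram, per-group polysome-membership frequencies.

    E.g. a tomogram with 7 ribosomes of one state of which 6 are associated
    in polysomes yields frequency 6/7 = 0.86.  Groups absent from a
    tomogram are omitted.
    """
    df = table.df
    member = [
        bool(links.membership.get((row.tomogram_id, int(row.particle_id)), False))
        for row in df.itertuples(index=False)
    ]
    work = df[["tomogram_id", group_by]].copy()
    work["member"] = member
    agg = (
        work.groupby(["tomogram_id", group_by], sort=False, observed=True)["member"]
        .agg(n_total="size", n_in_polysome="sum")
        .reset_index()
        .rename(columns={group_by: "group"})
    )
    agg["frequency"] = agg["n_in_polysome"] / agg["n_total"]
    return agg
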