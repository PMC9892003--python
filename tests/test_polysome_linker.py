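"""Direction masks, reciprocal link confirmation, chains, frequencies."""

import dataclasses

import numpy as np
import pytest

from conftest import make_table
from polyneigh.neighborhood_map import (
    HistogramGeometry,
    Neighbor,
    NeighborSet,
    ProbabilityHistogram,
    find_neighbors,
)
from polyneigh.polysome_linker import (
    AmbiguousClusterError,
    DirectionMask,
    MaskParams,
    PolysomeEdge,
    PolysomeLinkSet,
    assemble_chains,
    build_direction_masks,
    confirm_links,
    per_tomogram_frequencies,
)

GEO = HistogramGeometry()
REFS = {"trailing": np.array([0.0, 1.0, 0.0]), "leading": np.array([0.0, -1.0, 0.0])}


def hist_with_counts(voxel_counts, total=None):
    counts = np.zeros(GEO.shape, dtype=np.int64)
    for (i, j, k), c in voxel_counts.items():
        counts[i, j, k] = c
    total = total if total is not None else int(counts.sum())
    return ProbabilityHistogram(GEO, counts, total_neighbors=total)


def empty_hist():
    return ProbabilityHistogram(GEO, np.zeros(GEO.shape, dtype=np.int64), 0)


def test_all_below_threshold_gives_empty_masks():
    h = hist_with_counts({(7, 10, 7): 1}, total=10_000)  # p = 1e-4 < 5e-4
    with pytest.warns(UserWarning, match="no voxel above threshold"):
        trailing, leading = build_direction_masks(h, empty_hist(), MaskParams(), REFS)
    assert not trailing.voxels.any() and not leading.voxels.any()


def test_direction_split_and_dilation_superset():
    # 10 counts at +y, 10 at -y, total 1000 -> p = 0.01 each
    h = hist_with_counts({(7, 11, 7): 10, (7, 3, 7): 10}, total=1000)
    with pytest.warns(UserWarning, match="soluble"):  # empty soluble histogram
        trailing, leading = build_direction_masks(h, empty_hist(), MaskParams(), REFS)
    assert trailing.voxels[7, 11, 7] and not trailing.voxels[7, 3, 7]
    assert leading.voxels[7, 3, 7] and not leading.voxels[7, 11, 7]
    # dilation by 2 voxels: each mask strictly contains its seed cluster
    with pytest.warns(UserWarning, match="soluble"):  # empty soluble histogram
        undilated_t, undilated_l = build_direction_masks(
            h, empty_hist(), dataclasses.replace(MaskParams(), dilation_voxels=0), REFS
        )
    assert np.all(trailing.voxels >= undilated_t.voxels)
    assert trailing.voxels.sum() > undilated_t.voxels.sum()


def test_mask_union_across_membrane_and_soluble():
    hm = hist_with_counts({(7, 11, 7): 10}, total=1000)
    hs = hist_with_counts({(10, 10, 7): 10}, total=1000)
    trailing, _ = build_direction_masks(hm, hs, MaskParams(), REFS)
    assert trailing.voxels[7, 11, 7] and trailing.voxels[10, 10, 7]


def test_ambiguous_component_raises():
    # cluster along +x: 45 deg from both +y and -y references... use refs at
    # +/-y and a centroid on the x axis -> angle difference 0 < 5 deg
    h = hist_with_counts({(11, 7, 7): 10}, total=1000)
    with pytest.raises(AmbiguousClusterError, match="component"):
        build_direction_masks(h, empty_hist(), MaskParams(), REFS)


def test_shot_noise_components_discarded():
    h = hist_with_counts({(7, 11, 7): 10, (11, 7, 7): 2}, total=1000)
    with pytest.warns(UserWarning, match="soluble"):  # empty soluble histogram
        trailing, leading = build_direction_masks(h, empty_hist(), MaskParams(), REFS)
    assert trailing.voxels[7, 11, 7]
    assert not trailing.voxels[11, 7, 7] and not leading.voxels[11, 7, 7]


def full_mask(direction, voxels):
    grid = np.zeros(GEO.shape, dtype=bool)
    for v in voxels:
        grid[v] = True
    return DirectionMask(GEO, grid, direction)


def pair_sets(vec_ij, vec_ji, d=54.1):
    """Two particles that see each other with the given frame vectors."""
    return [
        NeighborSet("t1", 0, (Neighbor(1, np.array(vec_ij), d, np.array(vec_ji)),)),
        NeighborSet("t1", 1, (Neighbor(0, np.array(vec_ji), d, np.array(vec_ij)),)),
    ]


TRAIL_MASK = full_mask("trailing", [(7, 11, 7)])  # +y = (0, 60, 0)
LEAD_MASK = full_mask("leading", [(7, 3, 7)])  # -y = (0, -60, 0)


def test_reciprocal_pair_confirmed_once():
    sets = pair_sets([0, 60, 0], [0, -60, 0])
    links = confirm_links(sets, TRAIL_MASK, LEAD_MASK)
    assert [(e.trailing_id, e.leading_id) for e in links.edges] == [(1, 0)]
    assert links.membership == {("t1", 0): True, ("t1", 1): True}


def test_forward_only_condition_yields_no_edge():
    # neighbor in trailing region of focal, but focal NOT in neighbor's leading
    sets = pair_sets([0, 60, 0], [60, 0, 0])
    links = confirm_links(sets, TRAIL_MASK, LEAD_MASK)
    assert links.edges == []
    assert not any(links.membership.values())


def test_asymmetric_retention_still_links():
    """The reciprocal check uses the inverse vector even when the neighbor
    set of the partner does not retain the focal particle."""
    sets = [
        NeighborSet(
            "t1", 0,
            (Neighbor(1, np.array([0.0, 60.0, 0.0]), 60.0, np.array([0.0, -60.0, 0.0])),),
        ),
        NeighborSet("t1", 1, ()),
    ]
    links = confirm_links(sets, TRAIL_MASK, LEAD_MASK)
    assert [(e.trailing_id, e.leading_id) for e in links.edges] == [(1, 0)]


def test_confirm_links_invariant_to_iteration_order():
    sets = pair_sets([0, 60, 0], [0, -60, 0])
    fwd = confirm_links(sets, TRAIL_MASK, LEAD_MASK)
    rev = confirm_links(list(reversed(sets)), TRAIL_MASK, LEAD_MASK)
    assert fwd.edges == rev.edges


def test_multiplicity_resolved_to_nearest():
    """Two trailing candidates for one focal: only the nearer is kept."""
    far = 80.0
    sets = [
        NeighborSet(
            "t1", 0,
            (
                Neighbor(1, np.array([0.0, 60.0, 0.0]), 60.0, np.array([0.0, -60.0, 0.0])),
                Neighbor(2, np.array([0.0, 60.0, 0.0]), far, np.array([0.0, -60.0, 0.0])),
            ),
        ),
        NeighborSet("t1", 1, (Neighbor(0, np.array([0.0, -60.0, 0.0]), 60.0, np.array([0.0, 60.0, 0.0])),)),
        NeighborSet("t1", 2, (Neighbor(0, np.array([0.0, -60.0, 0.0]), far, np.array([0.0, 60.0, 0.0])),)),
    ]
    links = confirm_links(sets, TRAIL_MASK, LEAD_MASK)
    assert [(e.trailing_id, e.leading_id) for e in links.edges] == [(1, 0)]


def test_edge_monotone_in_mask_inclusion():
    sets = pair_sets([0, 60, 0], [0, -60, 0])
    bigger_trail = full_mask("trailing", [(7, 11, 7), (7, 12, 7)])
    links_small = confirm_links(sets, TRAIL_MASK, LEAD_MASK)
    links_big = confirm_links(sets, bigger_trail, LEAD_MASK)
    assert set((e.trailing_id, e.leading_id) for e in links_small.edges) <= set(
        (e.trailing_id, e.leading_id) for e in links_big.edges
    )


def linkset(edges):
    membership = {}
    for t, a, b, _ in edges:
        membership[(t, a)] = True
        membership[(t, b)] = True
    return PolysomeLinkSet(
        edges=[PolysomeEdge(t, a, b, d) for t, a, b, d in edges],
        membership=membership,
    )


def test_chain_assembly_path():
    links = assemble_chains(linkset([("t1", 0, 1, 50.0), ("t1", 1, 2, 50.0)]))
    assert links.chains == [[("t1", 0), ("t1", 1), ("t1", 2)]]


def test_chain_assembly_no_edges():
    links = assemble_chains(PolysomeLinkSet(edges=[], membership={}))
    assert links.chains == []


def test_cycle_broken_at_longest_edge(caplog):
    import logging

    with caplog.at_level(logging.WARNING):
        links = assemble_chains(
            linkset([("t1", 0, 1, 50.0), ("t1", 1, 2, 50.0), ("t1", 2, 0, 70.0)])
        )
    assert len(links.chains) == 1
    assert links.chains[0] == [("t1", 0), ("t1", 1), ("t1", 2)]
    assert len(links.edges) == 2  # the 70 A edge was removed
    assert any("breaking polysome cycle" in r.message for r in caplog.records)
    assert all(links.membership.values())


def test_per_tomogram_frequency_worked_example():
    """7 ribosomes of one state, 6 in polysomes -> frequency 0.86."""
    rows = [("t42", i, float(i) * 200, 0, 0, 0, 0, 0, "pre+", "SEC61-TRAP")
            for i in range(7)]
    table = make_table(rows)
    membership = {("t42", i): i < 6 for i in range(7)}
    links = PolysomeLinkSet(edges=[], membership=membership)
    freqs = per_tomogram_frequencies(table, links, group_by="state_label")
    assert len(freqs) == 1
    assert round(float(freqs.frequency.iloc[0]), 2) == 0.86


@pytest.mark.parametrize("n_members,expected", [(0, 0.0), (5, 1.0)])
def test_frequency_extremes(n_members, expected):
    rows = [("t1", i, float(i) * 200, 0, 0, 0, 0, 0, "pre", "SEC61-TRAP")
            for i in range(5)]
    table = make_table(rows)
    links = PolysomeLinkSet(
        edges=[], membership={("t1", i): i < n_members for i in range(5)}
    )
    freqs = per_tomogram_frequencies(table, links, group_by="state_label")
    assert float(freqs.frequency.iloc[0]) == expected


def test_end_to_end_planted_chain_recovery():
    """A planted 5-ribosome chain with sub-half-voxel jitter yields 4 edges."""
    rng = np.random.default_rng(3)
    rows = []
    for i in range(5):
        jitter = rng.uniform(-3.0, 3.0, 3)  # relative offsets stay < half a voxel
        rows.append(
            ("t1", i, 60.0 * i + jitter[0], jitter[1], jitter[2], 0.0, 0.0, 0.0)
        )
    table = make_table(rows)
    sets = find_neighbors(table)
    trailing = full_mask("trailing", [(11, 7, 7)])  # +x
    leading = full_mask("leading", [(3, 7, 7)])  # -x
    links = confirm_links(sets, trailing, leading)
    assert len(links.edges) == 4
    chains = assemble_chains(links)
    assert len(chains.chains) == 1 and len(chains.chains[0]) == 5
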