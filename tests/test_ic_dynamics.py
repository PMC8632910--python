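"""Event detection, exchange counting, trajectories, displacement fields."""

import networkx as nx
import numpy as np
import pytest

from omtrack.ic_dynamics import (
    EventRecord,
    count_events_binned,
    count_neighbor_exchange,
    detect_delaminations,
    detect_divisions,
    displacement_field,
    ic_trajectories,
)
from omtrack.io import CellGraphSequence
from omtrack.presets import GOF, LOF, WILD_TYPE
from omtrack.synthetic import generate_event_ledger, plant_t1


def _static_sequence(n_frames=5, n_cells=6):
    g = nx.cycle_graph(range(1, n_cells + 1))
    nx.set_node_attributes(g, 4.0, "area")
    return CellGraphSequence([g.copy() for _ in range(n_frames)],
                             {i: None for i in range(1, n_cells + 1)})


# ---------------------------------------------------------------------------
# planted-event recovery


def test_detectors_recover_planted_events_exactly(wt_ledger):
    """Precision = recall = 1 on noiseless ledgers, per ommatidium."""
    seqs, truth = wt_ledger
    for seq in seqs:
        key = lambda e: (e.frame, e.cells)
        assert detect_divisions(seq) == sorted(
            truth.events_of("division", seq.ommatidium), key=key)
        assert detect_delaminations(seq) == sorted(
            truth.events_of("delamination", seq.ommatidium), key=key)


def test_exchange_counts_equal_planted_schedule(wt_ledger):
    seqs, truth = wt_ledger
    for seq in seqs:
        counts, fraction, _ = count_neighbor_exchange(
            seq, truth.first_level[seq.ommatidium])
        assert np.array_equal(counts, truth.exchange_per_pair)
        assert np.all((0 <= fraction) & (fraction <= 1))
    # wild-type schedule declines from 7 to 4 events/ommatidium
    assert truth.exchange_per_pair[0] == 7
    assert truth.exchange_per_pair[-1] == 4


def test_zero_event_schedule_yields_empty_ledgers():
    from dataclasses import replace

    quiet = replace(WILD_TYPE, exchange_rate_start=0.0, exchange_rate_end=0.0,
                    division_schedule=(0,), delamination_schedule=(0,))
    seqs, truth = generate_event_ledger(quiet, n_frames=12, seed=3)
    assert truth.events == []
    seq = seqs[0]
    assert detect_divisions(seq) == []
    assert detect_delaminations(seq) == []
    counts, _, _ = count_neighbor_exchange(seq, truth.first_level[0])
    assert np.all(counts == 0)


def test_division_counts_decline_to_zero_after_cessation(wt_ledger):
    """Divisions follow the early-bin schedule and stop after ~250 min."""
    seqs, truth = wt_ledger
    events = detect_divisions(seqs[0])
    stats = count_events_binned(events, {0: truth.first_level[0]}, seqs[0].n_frames,
                                lineage_by_ommatidium={0: seqs[0].lineage})
    assert np.array_equal(stats.mean[:3], truth.division_per_bin[:3])
    assert np.all(stats.mean[3:] == 0)


# ---------------------------------------------------------------------------
# exchange scoring semantics


def test_static_graph_has_no_exchanges():
    seq = _static_sequence()
    counts, _, _ = count_neighbor_exchange(seq, {1, 2, 3})
    assert np.all(counts == 0)


def test_planted_t1_scores_both_first_level_cells():
    counts, fraction, events = count_neighbor_exchange(plant_t1(), {1, 2})
    assert counts.tolist() == [2]
    assert fraction[0] == pytest.approx(1.0)
    assert {e.cells[0] for e in events} == {1, 2}


def test_division_alone_does_not_score_as_exchange():
    """Daughters remapped to the parent leave every neighbor set unchanged."""
    g0 = nx.Graph()
    g0.add_nodes_from([1, 2, 3, 4], area=4.0)
    g0.add_edges_from([(1, 2), (2, 3), (3, 4), (4, 1)])
    g1 = nx.Graph()
    g1.add_nodes_from([2, 3, 4, 10, 11], area=4.0)
    g1.nodes[10]["area"] = g1.nodes[11]["area"] = 2.0
    g1.add_edges_from([(10, 2), (11, 4), (10, 11), (2, 3), (3, 4)])
    seq = CellGraphSequence([g0, g1], {1: None, 2: None, 3: None, 4: None,
                                       10: 1, 11: 1})
    counts, _, _ = count_neighbor_exchange(seq, {1, 2, 3, 4})
    assert np.all(counts == 0)


def test_delamination_alone_does_not_score_as_exchange():
    g0 = nx.Graph()
    g0.add_nodes_from([1, 2, 3, 4], area=4.0)
    g0.add_edges_from([(1, 2), (2, 3), (3, 4), (4, 1)])
    g1 = g0.copy()
    g1.remove_node(3)
    seq = CellGraphSequence([g0, g1], {i: None for i in range(1, 5)})
    counts, _, _ = count_neighbor_exchange(seq, {1, 2, 3, 4})
    assert np.all(counts == 0)


def test_untracked_id_raises_consistency_error():
    g0 = nx.Graph()
    g0.add_node(1, area=4.0)
    g1 = g0.copy()
    g1.add_node(99, area=4.0)
    seq = CellGraphSequence([g0, g1], {1: None})
    with pytest.raises(ValueError, match="untracked"):
        count_neighbor_exchange(seq, {1})


def test_lineage_cycle_is_a_format_error():
    g = nx.Graph()
    g.add_nodes_from([1, 2], area=4.0)
    seq = CellGraphSequence([g, g.copy()], {1: 2, 2: 1})
    with pytest.raises(ValueError, match="cycle"):
        detect_divisions(seq)


def test_track_ending_at_last_frame_is_censored():
    """A cell that shrinks into the final frame is not scored (censored)."""
    graphs = []
    areas = [4.0, 4.0, 2.0, 1.0, 0.4]
    for a in areas:
        g = nx.Graph()
        g.add_node(1, area=a)
        g.add_node(2, area=4.0)
        g.add_edge(1, 2)
        graphs.append(g)
    seq = CellGraphSequence(graphs, {1: None, 2: None})
    assert detect_delaminations(seq) == []


# ---------------------------------------------------------------------------
# binned statistics


def test_binned_single_ommatidium_sem_zero_convention():
    events = [EventRecord("division", f, (100 + f, 300 + f, 301 + f), 0)
              for f in (1, 3, 5)]
    lineage = {}
    stats = count_events_binned(events, {0: {101, 103, 105}}, n_frames=10,
                                lineage_by_ommatidium={0: lineage})
    assert stats.mean[0] == pytest.approx(3.0)
    assert stats.sem[0] == 0.0


def test_binned_two_ommatidia_hand_formula():
    events = ([EventRecord("delamination", 1, (101,), 0)] * 1 +
              [EventRecord("delamination", 2, (102,), 0)] +
              [EventRecord("delamination", f, (200 + f,), 1) for f in (1, 2, 3, 4)])
    stats = count_events_binned(
        events, {0: {101, 102}, 1: {201, 202, 203, 204}}, n_frames=10)
    assert stats.mean[0] == pytest.approx(3.0)  # counts 2 and 4
    assert stats.sem[0] == pytest.approx(1.0)  # SD sqrt(2) / sqrt(2)


# ---------------------------------------------------------------------------
# trajectories and displacement field


def test_motility_zero_ics_barely_move():
    """With planted motility 0, measured IC movement reduces to the passive
    deformation induced by cluster constriction; on a fully frozen field it
    vanishes exactly."""
    from dataclasses import replace

    from omtrack.synthetic import generate_tissue_movie

    frozen = replace(WILD_TYPE, ic_motility_um_per_frame=0.0, pulse_amplitude=0.0,
                     rotation_amplitude_deg=1e-9, area_amplitude_um2=1e-6)
    movie, ann, _ = generate_tissue_movie(frozen, n_frames=17, seed=5)
    trajs = ic_trajectories(movie, ann, window_min=120.0)
    for traj in trajs.values():
        assert np.linalg.norm(traj[-1] - traj[0]) < 1e-9

    still = replace(WILD_TYPE, ic_motility_um_per_frame=0.0)
    movie, ann, _ = generate_tissue_movie(still, n_frames=17, seed=5)
    trajs = ic_trajectories(movie, ann, window_min=120.0)
    nets = [np.linalg.norm(t[-1] - t[0]) for t in trajs.values()]
    assert np.mean(nets) < 0.05  # passive boundary deformation only
    assert max(nets) < 0.2


def test_fluidity_presets_order_mean_displacement(fluidity_movies):
    nets = {}
    for name, (movie, ann, _) in fluidity_movies.items():
        trajs = ic_trajectories(movie, ann, window_min=120.0)
        _, net = displacement_field(trajs, frame_interval_min=movie.frame_interval_min)
        nets[name] = np.mean(list(net.values()))
    assert nets["gof"] > nets["lof"]


def test_identical_trajectories_fill_grid_with_that_vector():
    v = np.array([0.4, -0.2])
    trajs = {i: np.array([[0.1 + i, 0.1], [0.1 + i, 0.1] + v]) for i in range(3)}
    fld, net = displacement_field(trajs, grid_um=1.25)
    occupied = fld.occupancy > 0
    assert occupied.sum() >= 1
    assert np.allclose(fld.vectors[occupied], v)
    assert all(abs(n - np.linalg.norm(v)) < 1e-12 for n in net.values())


def test_opposite_displacements_cancel():
    trajs = {
        1: np.array([[0.2, 0.2], [1.2, 0.2]]),
        2: np.array([[0.3, 0.3], [-0.7, 0.3]]),
    }
    fld, _ = displacement_field(trajs, grid_um=1.25)
    iy, ix = np.nonzero(fld.occupancy == 2)
    assert np.allclose(fld.vectors[iy, ix], 0.0)


def test_occupancy_weighted_mean_conserves_pooled_step_mean():
    rng = np.random.default_rng(9)
    trajs = {i: np.cumsum(rng.normal(0, 0.5, size=(8, 2)), axis=0)
             for i in range(10)}
    fld, _ = displacement_field(trajs, grid_um=1.0)
    occ = fld.occupancy
    weighted = np.nansum(fld.vectors * occ[..., None], axis=(0, 1)) / occ.sum()
    steps = np.vstack([np.diff(t, axis=0) for t in trajs.values()])
    assert np.allclose(weighted, steps.mean(axis=0), atol=1e-9)


def test_empty_trajectories_rejected():
    with pytest.raises(ValueError):
        displacement_field({})
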