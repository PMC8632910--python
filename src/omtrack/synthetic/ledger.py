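"""Abstract cell-graph event ledgers with planted, exactly-known events.

A ledger is a sequence of per-frame adjacency graphs for one ommatidium:
the eight cluster cells (ids 1-8), a ring of first-level interommatidial
cells (ICs) adjacent to the cluster, and an outer ring of second-level
cells. Events are planted per the preset's schedules:

* neighbor exchanges — per frame-pair, ``k(t)`` first-level ICs each toggle
  an adjacency with an outer cell, where ``k(t)`` declines linearly from
  ``exchange_rate_start`` to ``exchange_rate_end`` (rounded). Single-focal
  toggles make the per-frame-pair count of exchanging first-level ICs
  exactly controllable.
* divisions — per 90-min bin, a first-level IC splits into two daughters
  that partition (and jointly cover) its neighbors, each with half its
  area.
* delaminations — per 90-min bin, a first-level IC shrinks monotonically
  over the preceding three frames to below a quarter of its typical area
  and disappears. No healing edges are added between its former neighbors,
  so a delamination alone never scores as an exchange.

Every planted event is returned in the ground truth, so detector recovery
can be asserted exactly (precision = recall = 1 on noiseless ledgers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from ..ic_dynamics import EventRecord
from ..io import CellGraphSequence
from ..presets import GenotypePreset

__all__ = ["LedgerGroundTruth", "generate_event_ledger", "plant_t1"]

N_FIRST_LEVEL = 18
N_OUTER = 36
IC_BASE_AREA_UM2 = 4.0


class GenerationError(RuntimeError):
    """Requested events exceed the available cells."""


@dataclass
class LedgerGroundTruth:
    """Planted events and schedules, per ommatidium."""

    events: list[EventRecord]
    exchange_per_pair: np.ndarray  # planted exchanging-IC count per frame-pair
    division_per_bin: np.ndarray
    delamination_per_bin: np.ndarray
    first_level: dict[int, frozenset[int]] = field(default_factory=dict)

    def events_of(self, kind: str, ommatidium: int | None = None) -> list[EventRecord]:
        return [e for e in self.events
                if e.kind == kind and (ommatidium is None or e.ommatidium == ommatidium)]


def _base_graph() -> tuple[nx.Graph, list[int], list[int]]:
    """Cluster (1-8) + first-level ring + outer ring, with areas."""
    g = nx.Graph()
    cluster = list(range(1, 9))
    first = [100 + i for i in range(N_FIRST_LEVEL)]
    outer = [200 + i for i in range(N_OUTER)]
    for n in cluster:
        g.add_node(n, area=2.5)
    for n in first + outer:
        g.add_node(n, area=IC_BASE_AREA_UM2)
    # cluster: hub R8 (id 8) + ring of the other seven
    ring = [1, 2, 3, 4, 5, 6, 7]
    for i, n in enumerate(ring):
        g.add_edge(n, ring[(i + 1) % len(ring)])
        g.add_edge(n, 8)
    # first-level ring: cycle, each adjacent to two cluster ring cells
    for i, n in enumerate(first):
        g.add_edge(n, first[(i + 1) % N_FIRST_LEVEL])
        g.add_edge(n, ring[i % 7])
        g.add_edge(n, ring[(i + 1) % 7])
    # outer ring: cycle, each first-level cell touches two outer cells
    for i, n in enumerate(outer):
        g.add_edge(n, outer[(i + 1) % N_OUTER])
    for i, n in enumerate(first):
        g.add_edge(n, outer[(2 * i) % N_OUTER])
        g.add_edge(n, outer[(2 * i + 1) % N_OUTER])
    return g, first, outer


def _exchange_schedule(preset: GenotypePreset, n_pairs: int) -> np.ndarray:
    lin = np.linspace(preset.exchange_rate_start, preset.exchange_rate_end, n_pairs)
    return np.rint(lin).astype(int)


def _bin_of(t_transition: int, interval_min: float, bin_width: float = 90.0) -> int:
    return int((t_transition * interval_min) // bin_width)


def generate_event_ledger(
    preset: GenotypePreset,
    n_frames: int = 31,
    n_ommatidia: int = 1,
    seed: int = 0,
) -> tuple[list[CellGraphSequence], LedgerGroundTruth]:
    """Generate per-ommatidium graph sequences with planted events.

    Division/delamination events are drawn from the preset's per-90-min-bin
    schedules; exchange counts decline linearly from start to end rate.
    Raises :class:`GenerationError` if the schedules demand more cells than
    the ring provides.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    n_pairs = n_frames - 1
    exch = _exchange_schedule(preset, n_pairs)
    interval = preset.frame_interval_min
    n_bins = _bin_of(n_pairs - 1, interval) + 1
    div_bins = np.array([
        preset.division_schedule[b] if b < len(preset.division_schedule) else 0
        for b in range(n_bins)
    ])
    del_bins = np.array([
        preset.delamination_schedule[b] if b < len(preset.delamination_schedule) else 0
        for b in range(n_bins)
    ])

    sequences: list[CellGraphSequence] = []
    all_events: list[EventRecord] = []
    first_level_map: dict[int, frozenset[int]] = {}

    for omm in range(n_ommatidia):
        g0, first, outer = _base_graph()
        first_level_map[omm] = frozenset(first)
        lineage: dict[int, int | None] = {n: None for n in g0.nodes}
        next_id = 300

        # assign event transitions within each bin (delaminations need 3
        # preceding frames for the area collapse)
        transitions_in_bin: dict[int, list[int]] = {}
        for t in range(n_pairs):
            transitions_in_bin.setdefault(_bin_of(t, interval), []).append(t)
        div_at: dict[int, int] = {}
        del_at: dict[int, int] = {}
        for b in range(n_bins):
            avail = transitions_in_bin.get(b, [])
            for _ in range(div_bins[b]):
                cand = [t for t in avail if div_at.get(t, 0) + del_at.get(t, 0) < 4]
                if not cand:
                    raise GenerationError("too many events scheduled in one bin")
                t = int(rng.choice(cand))
                div_at[t] = div_at.get(t, 0) + 1
            for _ in range(del_bins[b]):
                # the collapse detector needs a few pre-shrink frames so the
                # running median reflects the healthy area: plant no
                # delamination before transition 5
                cand = [t for t in avail
                        if t >= 5 and div_at.get(t, 0) + del_at.get(t, 0) < 4]
                if not cand:
                    cand = [t for t in avail if t >= 5]
                if not cand:
                    raise GenerationError(
                        "delamination scheduled too early in the movie"
                    )
                t = int(rng.choice(cand))
                del_at[t] = del_at.get(t, 0) + 1

        # pre-assign delaminating cells so their shrink can start 3 frames early
        first_alive = list(first)
        shrink_plan: dict[int, tuple[int, float]] = {}  # cell -> (removal transition, base area)
        reserved: set[int] = set()
        for t in sorted(del_at):
            for _ in range(del_at[t]):
                cand = [c for c in first_alive if c not in reserved]
                if not cand:
                    raise GenerationError("not enough first-level cells to delaminate")
                c = int(rng.choice(cand))
                reserved.add(c)
                shrink_plan[c] = (t, IC_BASE_AREA_UM2)

        graphs = [g0]
        g = g0
        for t in range(n_pairs):
            g = g.copy()
            engaged: set[int] = set()

            # divisions
            for _ in range(div_at.get(t, 0)):
                cand = [c for c in g.nodes
                        if c in set(first_alive) and c not in engaged
                        and c not in reserved]
                if not cand:
                    raise GenerationError("not enough first-level cells to divide")
                parent = int(rng.choice(cand))
                engaged.add(parent)
                nbrs = sorted(g.neighbors(parent))
                half = max(1, len(nbrs) // 2)
                d1, d2 = next_id, next_id + 1
                next_id += 2
                area = g.nodes[parent].get("area", IC_BASE_AREA_UM2) / 2.0
                g.remove_node(parent)
                g.add_node(d1, area=area)
                g.add_node(d2, area=area)
                for nb in nbrs[:half]:
                    g.add_edge(d1, nb)
                for nb in nbrs[half:]:
                    g.add_edge(d2, nb)
                g.add_edge(d1, d2)
                lineage[d1] = parent
                lineage[d2] = parent
                first_alive.remove(parent)
                first_alive.extend([d1, d2])
                # fresh daughters only exist from the next frame on: they
                # cannot host another event in this same transition
                engaged.update((d1, d2))
                all_events.append(EventRecord("division", t, (parent, d1, d2), omm))

            # delaminations and scheduled shrinking
            for c, (t_rm, base_area) in list(shrink_plan.items()):
                if t == t_rm:
                    g.remove_node(c)
                    first_alive.remove(c)
                    del shrink_plan[c]
                    engaged.add(c)
                    all_events.append(EventRecord("delamination", t, (c,), omm))
                elif t_rm - 3 <= t < t_rm and c in g.nodes:
                    # monotone collapse: 0.55, 0.30, 0.12 of the base area
                    step = 3 - (t_rm - t)
                    g.nodes[c]["area"] = base_area * (0.55, 0.30, 0.12)[step]
                    engaged.add(c)

            # neighbor exchanges: single-focal edge toggles to outer cells.
            # At most one focal per first-level root so the detector's count
            # of distinct exchanging ICs equals the planted count exactly.
            k = int(exch[t])

            def _root(c: int) -> int:
                cur = c
                while cur not in frozenset(first):
                    cur = lineage[cur]
                return cur

            by_root: dict[int, int] = {}
            for c in first_alive:
                if c in g.nodes and c not in engaged:
                    by_root.setdefault(_root(c), c)
            focal_cand = list(by_root.values())
            if len(focal_cand) < k:
                raise GenerationError(
                    f"exchange schedule needs {k} free first-level cells at "
                    f"frame-pair {t}, only {len(focal_cand)} available"
                )
            focals = rng.choice(focal_cand, size=k, replace=False) if k else []
            outer_alive = [c for c in outer if c in g.nodes and c not in engaged]
            for c in focals:
                c = int(c)
                root = _root(c)
                # the detector compares lineage-remapped neighbor unions, so
                # the toggle must change the union over the whole sibling
                # family, not just the focal cell's own edge set
                family = [x for x in first_alive if x in g.nodes and _root(x) == root]
                partner = int(rng.choice(outer_alive))
                linked = [x for x in family if g.has_edge(x, partner)]
                if linked:
                    for x in linked:
                        g.remove_edge(x, partner)
                else:
                    g.add_edge(c, partner)
                all_events.append(EventRecord("exchange", t, (root,), omm))
            graphs.append(g)

        sequences.append(CellGraphSequence(graphs, dict(lineage), interval, omm))

    truth = LedgerGroundTruth(
        events=all_events,
        exchange_per_pair=exch,
        division_per_bin=div_bins,
        delamination_per_bin=del_bins,
        first_level=first_level_map,
    )
    return sequences, truth


def plant_t1(first_level: tuple[int, int] = (1, 2),
             others: tuple[int, int] = (3, 4)) -> CellGraphSequence:
    """A minimal two-frame T1 among four cells.

    Frame 0: the quad {a, b, c, d} with diagonal a-b; frame 1: the diagonal
    flips to c-d — the canonical neighbor exchange. ``first_level`` names
    the two focal cells (a, b) that lose each other.
    """
    a, b = first_level
    c, d = others
    g0 = nx.Graph()
    for n in (a, b, c, d):
        g0.add_node(n, area=IC_BASE_AREA_UM2)
    g0.add_edges_from([(a, c), (a, d), (b, c), (b, d), (a, b)])
    g1 = g0.copy()
    g1.remove_edge(a, b)
    g1.add_edge(c, d)
    lineage = {n: None for n in (a, b, c, d)}
    return CellGraphSequence([g0, g1], lineage)
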