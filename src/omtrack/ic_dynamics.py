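"""Interommatidial-cell (IC) event scoring and motility fields.

Divisions and delaminations are detected from track lineage and area
collapse; neighbor exchanges are scored per frame-pair as a change in a
first-level IC's neighbor-identity set after lineage remapping (daughters
mapped back to their parent) and after discarding ids absent from either
frame — so a division or delamination alone never scores as an exchange.
Division/delamination counts are binned per ommatidium into 90-min bins
(mean +- SEM across ommatidia). IC trajectories are positions relative to
the instantaneous cluster centroid; pooled trajectories are averaged on a
1.25-um grid to give the displacement/speed field of the tissue flow
around the cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import griddata

from .io import CellGraphSequence, TrackedTissueMovie, build_cell_graph, movie_to_graph_sequence

__all__ = [
    "EventRecord",
    "BinnedEventStats",
    "DisplacementField",
    "detect_divisions",
    "detect_delaminations",
    "count_events_binned",
    "count_neighbor_exchange",
    "ic_trajectories",
    "displacement_field",
]


@dataclass(frozen=True)
class EventRecord:
    """One scored cell event.

    ``frame`` is the index of the frame-pair start (the last frame at which
    the parent / dying cell is present). Divisions carry
    (parent, daughter1, daughter2); delaminations carry (cell,); exchanges
    carry the focal first-level cell(s).
    """

    kind: str  # "division" | "delamination" | "exchange"
    frame: int
    cells: tuple[int, ...]
    ommatidium: int = 0

    def __post_init__(self):
        if self.kind == "division" and len(self.cells) != 3:
            raise ValueError("division needs (parent, daughter, daughter)")
        if self.kind == "delamination" and len(self.cells) != 1:
            raise ValueError("delamination involves exactly one cell")
        if self.kind == "exchange" and len(self.cells) < 1:
            raise ValueError("exchange needs at least one focal cell")


@dataclass
class BinnedEventStats:
    """Per-90-min-bin mean events/ommatidium with SEM across ommatidia."""

    bin_edges_min: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_ommatidia: int

    def __post_init__(self):
        if np.any(self.sem < 0):
            raise ValueError("SEM must be non-negative")


@dataclass
class DisplacementField:
    """Grid-averaged displacement vectors and speeds around the cluster.

    The cluster sits at the origin. ``vectors[iy, ix]`` is the mean step
    displacement (um) of ICs passing through the grid cell; unoccupied
    cells are NaN. ``fine_speed`` is the bilinear interpolation of the
    speed (um/min) onto a 4x finer grid over the occupied support.
    """

    origin_um: np.ndarray
    spacing_um: float
    vectors: np.ndarray  # (ny, nx, 2)
    occupancy: np.ndarray  # (ny, nx)
    speed: np.ndarray  # (ny, nx)
    fine_xy: tuple[np.ndarray, np.ndarray] | None = None
    fine_speed: np.ndarray | None = None


def _as_sequence(data) -> CellGraphSequence:
    if isinstance(data, TrackedTissueMovie):
        return movie_to_graph_sequence(data)
    return data


def _check_lineage(lineage: dict[int, int | None]) -> None:
    for start in lineage:
        seen = set()
        node: int | None = start
        while node is not None:
            if node in seen:
                raise ValueError(f"lineage cycle involving cell {start}")
            seen.add(node)
            node = lineage.get(node)


# ---------------------------------------------------------------------------
# division / delamination detection


def detect_divisions(data, area_ratio_bounds=(0.6, 1.4)) -> list[EventRecord]:
    """Divisions: a track's lineage splits into exactly two daughters.

    The daughters must appear in the frame after the parent's last frame,
    with a combined first-frame area within ``area_ratio_bounds`` of the
    parent's last area, and both adjacent to the parent's footprint
    (sharing at least one former neighbor of the parent, or each other).
    """
    seq = _as_sequence(data)
    _check_lineage(seq.lineage)
    last_frame = {}
    first_frame = {}
    for f, g in enumerate(seq.graphs):
        for n in g.nodes:
            first_frame.setdefault(n, f)
            last_frame[n] = f
    children: dict[int, list[int]] = {}
    for child, parent in seq.lineage.items():
        if parent is not None:
            children.setdefault(parent, []).append(child)
    events = []
    for parent, kids in children.items():
        if len(kids) != 2 or parent not in last_frame:
            continue
        f = last_frame[parent]
        if f + 1 >= seq.n_frames:
            continue
        if any(first_frame.get(k) != f + 1 for k in kids):
            continue
        g0, g1 = seq.graphs[f], seq.graphs[f + 1]
        parent_area = g0.nodes[parent].get("area")
        kid_area = sum(g1.nodes[k].get("area", np.nan) for k in kids)
        if parent_area and np.isfinite(kid_area):
            ratio = kid_area / parent_area
            if not (area_ratio_bounds[0] <= ratio <= area_ratio_bounds[1]):
                continue
        footprint = set(g0.neighbors(parent))
        ok = all(
            (set(g1.neighbors(k)) & (footprint | set(kids))) - {k}
            for k in kids
        )
        if ok:
            events.append(EventRecord("division", f, (parent, *sorted(kids)),
                                      seq.ommatidium))
    return sorted(events, key=lambda e: (e.frame, e.cells))


def detect_delaminations(data, collapse_fraction: float = 0.25,
                         n_collapse_frames: int = 3) -> list[EventRecord]:
    """Delaminations: a track ends with no daughters after apical collapse.

    The cell's area over the preceding ``n_collapse_frames`` frames must
    decrease monotonically and end below ``collapse_fraction`` of the
    track's running median area. Tracks that end at the last movie frame
    are censored, not scored.
    """
    seq = _as_sequence(data)
    _check_lineage(seq.lineage)
    parents_with_kids = {p for p in seq.lineage.values() if p is not None}
    area_hist: dict[int, list[float]] = {}
    last_frame: dict[int, int] = {}
    for f, g in enumerate(seq.graphs):
        for n, d in g.nodes(data=True):
            area_hist.setdefault(n, []).append(float(d.get("area", np.nan)))
            last_frame[n] = f
    events = []
    for n, f in last_frame.items():
        if f >= seq.n_frames - 1 or n in parents_with_kids:
            continue
        areas = np.asarray(area_hist[n])
        if areas.size < n_collapse_frames or np.any(~np.isfinite(areas)):
            continue
        tail = areas[-n_collapse_frames:]
        if not np.all(np.diff(tail) < 0):
            continue
        if tail[-1] < collapse_fraction * float(np.median(areas)):
            events.append(EventRecord("delamination", f, (n,), seq.ommatidium))
    return sorted(events, key=lambda e: (e.frame, e.cells))


# ---------------------------------------------------------------------------
# binned statistics


def count_events_binned(events, first_level_by_ommatidium, n_frames: int,
                        frame_interval_min: float = 10.0,
                        bin_width_min: float = 90.0,
                        lineage_by_ommatidium=None) -> BinnedEventStats:
    """Mean +- SEM events per ommatidium in contiguous 90-min bins.

    Only events whose focal cell is (or descends from) a first-level IC of
    its ommatidium are counted. With a single ommatidium the SEM is
    reported as 0 by convention. Events outside the movie span are dropped
    with a warning.
    """
    omm_ids = sorted(first_level_by_ommatidium)
    total_min = n_frames * frame_interval_min
    edges = np.arange(0.0, total_min + bin_width_min, bin_width_min)
    counts = np.zeros((len(omm_ids), edges.size - 1))
    for ev in events:
        if ev.ommatidium not in first_level_by_ommatidium:
            continue
        first = set(first_level_by_ommatidium[ev.ommatidium])
        lineage = (lineage_by_ommatidium or {}).get(ev.ommatidium, {})
        focal = ev.cells[0]
        node: int | None = focal
        while node is not None and node not in first:
            node = lineage.get(node)
        if node is None:
            continue
        t = ev.frame * frame_interval_min
        if not (0 <= t < total_min):
            warnings.warn(f"event at t={t} min outside movie span; dropped",
                          stacklevel=2)
            continue
        b = min(int(t // bin_width_min), edges.size - 2)
        counts[omm_ids.index(ev.ommatidium), b] += 1
    mean = counts.mean(axis=0)
    if len(omm_ids) > 1:
        sem = counts.std(axis=0, ddof=1) / np.sqrt(len(omm_ids))
    else:
        sem = np.zeros_like(mean)  # n = 1 convention
    return BinnedEventStats(edges, mean, sem, len(omm_ids))


# ---------------------------------------------------------------------------
# neighbor exchange


def _representative(node: int, lineage: dict, present: set[int]) -> int | None:
    """Walk lineage upward until reaching an id present in ``present``."""
    seen = set()
    cur: int | None = node
    while cur is not None and cur not in present:
        if cur in seen:
            raise ValueError("lineage cycle")
        seen.add(cur)
        cur = lineage.get(cur)
    return cur


def count_neighbor_exchange(data, annotation_or_first_level):
    """Per-frame-pair count N(t) of first-level ICs changing neighbors.

    For each frame-pair (t, t+1), ids at t+1 are remapped to their t-frame
    ancestors (so daughters stand in for their divided parent), ids absent
    from either frame are discarded from both neighbor sets, and a
    first-level IC scores if its remaining neighbor-identity set changed.
    Returns (N, fraction, events) with fraction = N(t) / first-level ICs
    alive at t.
    """
    seq = _as_sequence(data)
    first = getattr(annotation_or_first_level, "first_level_ics",
                    annotation_or_first_level)
    first = set(first)
    lineage = seq.lineage
    _check_lineage(lineage)
    n_pairs = seq.n_frames - 1
    counts = np.zeros(n_pairs, dtype=int)
    fraction = np.zeros(n_pairs)
    events: list[EventRecord] = []
    for t in range(n_pairs):
        g0, g1 = seq.graphs[t], seq.graphs[t + 1]
        present0 = set(g0.nodes)
        for n in g1.nodes:
            if n not in present0 and _representative(n, lineage, present0) is None:
                raise ValueError(f"untracked id {n} appears in frame {t + 1}")
        # map t+1 nodes onto their t-frame representatives
        carriers: dict[int, set[int]] = {}
        for m in g1.nodes:
            rep = _representative(m, lineage, present0)
            if rep is not None:
                carriers.setdefault(rep, set()).add(m)
        alive_both = set(carriers)

        def root_first(n: int) -> int | None:
            return _representative(n, lineage, first)

        focal_nodes = [n for n in g0.nodes if root_first(n) is not None]
        alive_roots = {root_first(n) for n in focal_nodes}
        scored_roots = set()
        for n in focal_nodes:
            if n not in alive_both:
                continue  # delaminated or lost: no exchange attributable
            set0 = {nb for nb in g0.neighbors(n) if nb in alive_both}
            set1 = set()
            for m in carriers[n]:
                for nb in g1.neighbors(m):
                    rep = _representative(nb, lineage, present0)
                    if rep is not None and rep != n and rep in alive_both:
                        set1.add(rep)
            if set0 != set1:
                scored_roots.add(root_first(n))
        counts[t] = len(scored_roots)
        fraction[t] = counts[t] / len(alive_roots) if alive_roots else 0.0
        for r in sorted(scored_roots):
            events.append(EventRecord("exchange", t, (r,), seq.ommatidium))
    return counts, fraction, events


# ---------------------------------------------------------------------------
# trajectories and displacement fields


def ic_trajectories(movie: TrackedTissueMovie, annotation, window_min: float = 120.0,
                    cells=None) -> dict[int, np.ndarray]:
    """IC centroid positions relative to the cluster centroid.

    Tracks interommatidial cells (cells annotated with role "IC"; cone
    cells travel with the cluster and carry no independent motility) from
    R7 recruitment up to ``window_min`` minutes after it; positions are
    relative to the instantaneous area-weighted centroid of the recruited
    R-cells (cluster at origin). Returns cell_id -> (n_steps, 2) um. The
    window is truncated (with a warning) if it exceeds the movie span.
    """
    r7 = int(annotation.r7_frame)
    n_steps = int(round(window_min / movie.frame_interval_min)) + 1
    if r7 + n_steps > movie.n_frames:
        warnings.warn("window exceeds movie span; truncating", stacklevel=2)
        n_steps = movie.n_frames - r7
    if cells is not None:
        ics = set(cells)
    else:
        ics = {cid for cid, role in annotation.roles.items() if role == "IC"}
        if not ics:
            ics = set(annotation.first_level_ics)
    out: dict[int, list] = {c: [] for c in ics}
    for f in range(r7, r7 + n_steps):
        geom = build_cell_graph(movie, f)
        rcells = [c for c in annotation.r_cells_at_frame(f) if c in geom.cells]
        w = np.array([geom.cells[c].area_um2 for c in rcells])
        pts = np.array([geom.cells[c].centroid_um for c in rcells])
        cluster = (pts * w[:, None]).sum(axis=0) / w.sum()
        for c in ics:
            if c in geom.cells:
                out[c].append(geom.cells[c].centroid_um - cluster)
    return {c: np.asarray(v) for c, v in out.items() if len(v) >= 2}


def displacement_field(trajectories: dict[int, np.ndarray], grid_um: float = 1.25,
                       frame_interval_min: float = 10.0,
                       refine: int = 4) -> tuple[DisplacementField, dict[int, float]]:
    """Grid-average the pooled IC trajectories around the origin.

    Each per-frame step displacement is assigned to the grid cell holding
    the step's start position; a grid cell's vector is the mean of the
    steps through it and its speed |vector| / frame interval. The speed is
    interpolated onto a ``refine``-times finer grid over the occupied
    support. Also returns each cell's net displacement magnitude (for
    violin-plot comparisons).
    """
    if grid_um <= 0:
        raise ValueError("grid spacing must be positive")
    if not trajectories:
        raise ValueError("need at least one trajectory")
    all_pts = np.vstack(list(trajectories.values()))
    origin = np.floor(all_pts.min(axis=0) / grid_um) * grid_um
    extent = np.ceil(all_pts.max(axis=0) / grid_um) * grid_um
    nx = max(int(round((extent[0] - origin[0]) / grid_um)), 1)
    ny = max(int(round((extent[1] - origin[1]) / grid_um)), 1)
    sums = np.zeros((ny, nx, 2))
    occ = np.zeros((ny, nx), dtype=int)
    net: dict[int, float] = {}
    for cid, traj in trajectories.items():
        net[cid] = float(np.linalg.norm(traj[-1] - traj[0]))
        steps = np.diff(traj, axis=0)
        cells_ix = np.clip(((traj[:-1] - origin) / grid_um).astype(int),
                           [0, 0], [nx - 1, ny - 1])
        for (ix, iy), d in zip(cells_ix, steps):
            sums[iy, ix] += d
            occ[iy, ix] += 1
    with np.errstate(invalid="ignore"):
        vectors = np.where(occ[..., None] > 0, sums / np.maximum(occ, 1)[..., None],
                           np.nan)
    speed = np.linalg.norm(vectors, axis=-1) / frame_interval_min
    # interpolate speed onto a finer grid over the occupied support
    fine_xy = None
    fine_speed = None
    cy, cx = np.nonzero(occ)
    if cy.size >= 3:
        centers = np.column_stack([
            origin[0] + (cx + 0.5) * grid_um,
            origin[1] + (cy + 0.5) * grid_um,
        ])
        fx = np.linspace(centers[:, 0].min(), centers[:, 0].max(), nx * refine)
        fy = np.linspace(centers[:, 1].min(), centers[:, 1].max(), ny * refine)
        fxx, fyy = np.meshgrid(fx, fy)
        fine_speed = griddata(centers, speed[cy, cx], (fxx, fyy), method="linear")
        fine_xy = (fx, fy)
    fld = DisplacementField(origin, grid_um, vectors, occ, speed, fine_xy, fine_speed)
    return fld, net
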