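"""Synthetic tracked tissue movies of a rotating, constricting cluster.

The tissue is a Voronoi tessellation of seed points in a square field:
eight cluster seeds (the eventual R1-R8 photoreceptors, five of which form
the initial pre-cluster) surrounded by interommatidial seeds on a jittered
hexagonal lattice. Per frame the cluster seeds are transformed rigidly —
rotated about the cluster centroid by the preset's rotation schedule and
scaled radially so that the analytic Voronoi area of the eight cluster
cells equals the area schedule A*(t) exactly (the scale is found by
root-finding per frame). Interommatidial seeds perform seeded random walks
at the preset motility, reflected at the field boundary and excluded from
the cluster's footprint. The tessellation is rasterized to uint16 label
images by nearest-seed assignment, which is exactly the Voronoi partition,
so polygon-level geometry and the rendered movie agree to rasterization
error.

Movies are kinematic: they carry no division/delamination/exchange events
(planted events live in the abstract graph ledgers of
:mod:`omtrack.synthetic.ledger`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.spatial import Voronoi, cKDTree

from ..io import OmmatidiumAnnotation, TrackedTissueMovie
from ..presets import GenotypePreset
from .schedules import area_schedule, rotation_schedule

__all__ = ["GroundTruth", "GeometryError", "generate_tissue_movie"]

# ring angles (deg, image coords) of the 7 peripheral cluster seeds; R8 is
# central. R2 and R5 are diametric so the R2-R5 line is parallel to a
# vertical furrow at frame 0 (R(0) = 0).
_RING_ANGLES = {
    "R2": 90.0, "R3": 140.0, "R4": 200.0, "R5": 270.0,
    "R6": 320.0, "R1": 10.0, "R7": 40.0,
}
_R_IDS = {f"R{i}": i for i in range(1, 9)}  # cell ids 1..8
N_CONE = 10  # accessory (cone-type) collar cells co-rotating with the cluster


class GeometryError(ValueError):
    """Requested tissue does not fit the field."""


@dataclass
class GroundTruth:
    """What the generator actually did, for round-trip testing."""

    time_min: np.ndarray
    rotation_deg: np.ndarray  # applied cluster rotation, relative to frame 0
    area_um2: np.ndarray  # calibrated 8-cell Voronoi area per frame
    seed_positions_um: dict[int, np.ndarray]  # cell_id -> (n_frames, 2)
    events: list = field(default_factory=list)
    params: dict = field(default_factory=dict)


def _hex_lattice(field_um: float, spacing: float, rng) -> np.ndarray:
    dy = spacing * np.sqrt(3.0) / 2.0
    pts = []
    y = spacing * 0.5
    row = 0
    while y < field_um:
        x0 = spacing * (0.25 + 0.5 * (row % 2))
        xs = np.arange(x0, field_um, spacing)
        pts.extend((x, y) for x in xs)
        y += dy
        row += 1
    pts = np.asarray(pts, dtype=float)
    return pts + rng.uniform(-0.15 * spacing, 0.15 * spacing, size=pts.shape)


def _mirrored_voronoi_areas(points: np.ndarray, field_um: float,
                            which: np.ndarray) -> np.ndarray:
    """Areas of the bounded Voronoi cells of ``points[which]``.

    Bounding is by mirroring all points across the four field edges, which
    makes every in-field region finite and clipped to the field.
    """
    w = field_um
    mirrors = [points.copy() for _ in range(4)]
    mirrors[0][:, 0] = -mirrors[0][:, 0]
    mirrors[1][:, 0] = 2 * w - mirrors[1][:, 0]
    mirrors[2][:, 1] = -mirrors[2][:, 1]
    mirrors[3][:, 1] = 2 * w - mirrors[3][:, 1]
    allpts = np.vstack([points] + mirrors)
    vor = Voronoi(allpts)
    areas = np.zeros(np.count_nonzero(which))
    for j, idx in enumerate(np.nonzero(which)[0]):
        region = vor.regions[vor.point_region[idx]]
        verts = vor.vertices[region]
        x, y = verts[:, 0], verts[:, 1]
        areas[j] = 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))
    return areas


def _rot(theta_deg: float) -> np.ndarray:
    th = np.radians(theta_deg)
    return np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])


def generate_tissue_movie(
    preset: GenotypePreset,
    n_frames: int = 31,
    seed: int = 0,
    field_um: float = 16.0,
    pixel_size_um: float = 0.04,
    ic_spacing_um: float = 1.9,
) -> tuple[TrackedTissueMovie, OmmatidiumAnnotation, GroundTruth]:
    """Generate a tracked, rendered tissue movie with known ground truth.

    Returns (movie, annotation, ground_truth). Cell ids 1..8 are the
    photoreceptors R1..R8; higher ids are interommatidial cells. The
    ground-truth rotation is the rigid rotation actually applied (relative
    to frame 0) and the ground-truth area is the calibrated analytic
    Voronoi area of the eight cluster cells, which follows the preset's
    A*(t) schedule.
    """
    if n_frames < 3:
        raise ValueError("need at least 3 frames")
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames, dtype=float) * preset.frame_interval_min

    rot_truth = rotation_schedule(t, preset, pulses=True)
    rot_applied = rot_truth - rot_truth[0]
    area_truth = area_schedule(t, preset, pulses=True)
    if np.any(area_truth <= 0):
        raise ValueError("area schedule must stay positive")

    center = np.array([field_um / 2.0, field_um / 2.0])
    cluster_r0 = float(np.sqrt(area_truth.max() / np.pi))
    if cluster_r0 * 2.0 + 4.0 * ic_spacing_um > field_um:
        raise GeometryError("cluster larger than field: increase field_um")

    # base cluster offsets (unit scale): R8 central, 7 photoreceptors on a
    # ring, and a collar of cone-type accessory cells that co-rotates and
    # co-contracts with the cluster. The collar encloses the photoreceptor
    # cells, so their Voronoi boundaries — hence centroids — rotate rigidly
    # with the cluster instead of dragging against the static IC field.
    ring_r = 0.55 * cluster_r0
    collar_r = 0.95 * cluster_r0
    n_rigid = 8 + N_CONE
    base = np.zeros((n_rigid, 2))
    for role, ang in _RING_ANGLES.items():
        a = np.radians(ang)
        base[_R_IDS[role] - 1] = ring_r * np.array([np.cos(a), np.sin(a)])
    cone_angles = np.radians(18.0 + 360.0 * np.arange(N_CONE) / N_CONE)
    base[8:] = collar_r * np.column_stack([np.cos(cone_angles), np.sin(cone_angles)])
    cone_ids = np.arange(9, 9 + N_CONE)

    # the 8-cell boundary sits midway between the photoreceptor ring and the
    # collar, both scaling with s: a good initial-scale estimate for
    # positioning the IC exclusion zone
    mid_r = 0.5 * (ring_r + collar_r)
    s_est = np.sqrt(area_truth / np.pi) / mid_r
    ic = _hex_lattice(field_um, ic_spacing_um, rng)
    r_excl0 = collar_r * float(s_est.max()) + 0.45
    ic = ic[np.linalg.norm(ic - center, axis=1) > r_excl0]
    n_ic = ic.shape[0]
    if n_ic < 12:
        raise GeometryError("field too small for an interommatidial neighborhood")
    ic_ids = np.arange(9 + N_CONE, 9 + N_CONE + n_ic)

    n_total = n_rigid + n_ic
    is_cluster = np.zeros(n_total, dtype=bool)
    is_cluster[:8] = True

    # rasterization grid (pixel centers)
    n_px = int(round(field_um / pixel_size_um))
    ax = (np.arange(n_px) + 0.5) * pixel_size_um
    gx, gy = np.meshgrid(ax, ax)  # gy = rows (y), gx = cols (x)
    grid = np.column_stack([gx.ravel(), gy.ravel()])

    frames: list[np.ndarray] = []
    positions = np.zeros((n_frames, n_total, 2))
    scale_lo, scale_hi = 0.02, 3.0
    ic_pos = ic.copy()
    step_sd = preset.ic_motility_um_per_frame / np.sqrt(2.0)

    for f in range(n_frames):
        if f > 0 and preset.ic_motility_um_per_frame > 0:
            steps = rng.normal(0.0, step_sd, size=ic_pos.shape)
            cand = ic_pos + steps
            # reflect at the field boundary
            cand = np.abs(cand)
            cand = field_um - np.abs(field_um - cand)
            # stay outside the cluster + collar footprint
            r_excl = collar_r * float(s_est[f]) + 0.3
            ok = np.linalg.norm(cand - center, axis=1) > r_excl
            ic_pos = np.where(ok[:, None], cand, ic_pos)

        rotated = base @ _rot(rot_applied[f]).T

        def cluster_area(s: float, rotated=rotated, ic_pos=ic_pos) -> float:
            pts = np.vstack([center + s * rotated, ic_pos])
            return float(_mirrored_voronoi_areas(pts, field_um, is_cluster).sum())

        target = area_truth[f]
        if (cluster_area(scale_lo) - target) * (cluster_area(scale_hi) - target) > 0:
            raise GeometryError(
                "area schedule unattainable with the current interommatidial "
                f"configuration at frame {f}"
            )
        s = optimize.brentq(lambda v: cluster_area(v) - target, scale_lo, scale_hi,
                            xtol=1e-7, rtol=1e-12)
        pts = np.vstack([center + s * rotated, ic_pos])
        positions[f] = pts

        labels = cKDTree(pts).query(grid)[1] + 1  # labels = cell ids
        frames.append(labels.reshape(n_px, n_px).astype(np.uint16))

    cell_ids = np.concatenate([np.arange(1, 9), cone_ids, ic_ids])
    rows = [
        {"frame": f, "label": int(cid), "cell_id": int(cid), "parent_id": -1}
        for f in range(n_frames)
        for cid in cell_ids
    ]
    movie = TrackedTissueMovie(
        frames=frames,
        pixel_size_um=pixel_size_um,
        tracks=pd.DataFrame(rows),
        frame_interval_min=preset.frame_interval_min,
    )

    roles = {i: f"R{i}" for i in range(1, 9)}
    roles.update({int(cid): "cone" for cid in cone_ids})
    roles.update({int(cid): "IC" for cid in ic_ids})
    annotation = OmmatidiumAnnotation(
        roles=roles,
        furrow_axis_deg=90.0,
        r7_frame=min(preset.r7_frame, n_frames - 1),
        r16_frame=min(preset.r16_frame, n_frames - 1),
        chirality="counterclockwise",
    )
    # freeze the first-level IC neighborhood at R7 recruitment
    from ..geometry import neighbor_levels
    from ..io import build_cell_graph

    geom = build_cell_graph(movie, int(annotation.r7_frame))
    first, _ = neighbor_levels(geom, annotation)
    annotation.first_level_ics = frozenset(first)

    truth = GroundTruth(
        time_min=t,
        rotation_deg=rot_applied,
        area_um2=area_truth,
        seed_positions_um={int(cid): positions[:, i, :]
                           for i, cid in enumerate(cell_ids)},
        params={"preset": preset.name, "seed": seed, "field_um": field_um,
                "pixel_size_um": pixel_size_um},
    )
    return movie, annotation, truth
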