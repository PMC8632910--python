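"""Reading, writing, and graph extraction for tracked tissue movies.

A tracked movie is a multi-page TIFF of integer label images (uint16,
0 = background) plus a tracking table (CSV: frame, label, cell_id,
parent_id) mapping per-frame labels to persistent cell identities, and an
ommatidium annotation (JSON: R1-R8 roles, furrow axis, R7 recruitment
frame, chirality). From each label frame we extract per-cell polygons
(sub-pixel boundary contours), areas, perimeters, centroids and the
neighbor graph (cells sharing at least one boundary pixel-edge,
4-connectivity — corner contact does not count).

Conventions: frames are 0-based; image coordinates are x-right / y-down;
centroids and polygons are reported in um; cells touching the image border
are flagged (their perimeter is truncated) and excluded from shape
statistics downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon
from skimage import measure

from .geometry import CellGeometry, FrameGeometry

__all__ = [
    "TrackedTissueMovie",
    "OmmatidiumAnnotation",
    "CellGraphSequence",
    "MovieFormatError",
    "read_movie",
    "write_movie",
    "read_annotation",
    "write_annotation",
    "build_cell_graph",
    "movie_to_graph_sequence",
]

PRECLUSTER_ROLES = ("R2", "R3", "R4", "R5", "R8")


class MovieFormatError(ValueError):
    """Tracking table and label images disagree, or the table is malformed."""


@dataclass
class TrackedTissueMovie:
    """Per-frame label images with persistent cell tracks and lineage."""

    frames: list[np.ndarray]
    pixel_size_um: float
    tracks: pd.DataFrame  # columns: frame, label, cell_id, parent_id
    frame_interval_min: float = 10.0

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if self.frame_interval_min <= 0:
            raise ValueError("frame interval must be positive")
        required = {"frame", "label", "cell_id", "parent_id"}
        if not required.issubset(self.tracks.columns):
            raise MovieFormatError(f"tracking table needs columns {sorted(required)}")
        self.validate()

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def validate(self) -> None:
        dup = self.tracks.duplicated(subset=["frame", "label"])
        if dup.any():
            raise MovieFormatError("duplicate (frame, label) rows in tracking table")
        dup_cell = self.tracks.duplicated(subset=["frame", "cell_id"])
        if dup_cell.any():
            raise MovieFormatError("a cell_id occupies more than one region in a frame")
        for f, sub in self.tracks.groupby("frame"):
            f = int(f)
            if f >= len(self.frames):
                raise MovieFormatError(f"tracking table references missing frame {f}")
            present = set(np.unique(self.frames[f])) - {0}
            missing = set(sub["label"].astype(int)) - present
            if missing:
                raise MovieFormatError(
                    f"labels {sorted(missing)} in tracking table absent from frame {f}"
                )

    def label_to_cell(self, frame: int) -> dict[int, int]:
        sub = self.tracks[self.tracks["frame"] == frame]
        return dict(zip(sub["label"].astype(int), sub["cell_id"].astype(int)))

    @property
    def lineage(self) -> dict[int, int | None]:
        """cell_id -> parent cell_id (None for founder cells)."""
        out: dict[int, int | None] = {}
        for _, row in self.tracks.drop_duplicates("cell_id").iterrows():
            p = row["parent_id"]
            out[int(row["cell_id"])] = None if pd.isna(p) or int(p) < 0 else int(p)
        return out


@dataclass
class OmmatidiumAnnotation:
    """Cell roles and alignment landmarks for one ommatidium.

    ``roles`` maps cell_id to one of R1..R8, "cone", or "IC". The furrow
    axis is the orientation (degrees, image coordinates) of the
    morphogenetic furrow line; rotation angles are measured against it.
    ``first_level_ics`` is the IC neighborhood frozen at R7 recruitment
    (cone cells included).
    """

    roles: dict[int, str]
    furrow_axis_deg: float = 90.0
    r7_frame: int | str = "unknown"
    r16_frame: int | str = "unknown"
    chirality: str = "counterclockwise"
    first_level_ics: frozenset[int] = frozenset()

    def __post_init__(self):
        for role in [f"R{i}" for i in range(1, 9)]:
            n = sum(1 for r in self.roles.values() if r == role)
            if n > 1:
                raise ValueError(f"role {role} assigned to {n} cells")
        r_ids = {cid for cid, r in self.roles.items() if r.startswith("R")}
        if set(self.first_level_ics) & r_ids:
            raise ValueError("first_level_ics must be disjoint from R-cells")
        if self.chirality not in ("clockwise", "counterclockwise"):
            raise ValueError("chirality must be clockwise or counterclockwise")

    def cell_for_role(self, role: str) -> int:
        for cid, r in self.roles.items():
            if r == role:
                return cid
        raise KeyError(f"no cell annotated as {role}")

    def r_cells_at_frame(self, frame: int) -> list[int]:
        """R-cells recruited by ``frame``: the 5-cell pre-cluster, then
        R1/R6, then R7."""
        roles = list(PRECLUSTER_ROLES)
        if self.r16_frame != "unknown" and frame >= int(self.r16_frame):
            roles += ["R1", "R6"]
        if self.r7_frame != "unknown" and frame >= int(self.r7_frame):
            roles += ["R7"]
        return [self.cell_for_role(r) for r in roles if r in self.roles.values()]


# ---------------------------------------------------------------------------
# movie read/write


def write_movie(movie: TrackedTissueMovie, tiff_path, tracks_path, meta_path=None) -> None:
    """Write label stack (multi-page uint16 TIFF), tracking CSV, metadata JSON."""
    stack = np.stack([f.astype(np.uint16) for f in movie.frames])
    tifffile.imwrite(str(tiff_path), stack)
    movie.tracks.to_csv(tracks_path, index=False)
    if meta_path is not None:
        Path(meta_path).write_text(json.dumps({
            "pixel_size_um": movie.pixel_size_um,
            "frame_interval_min": movie.frame_interval_min,
        }, indent=1))


def read_movie(tiff_path, tracks_path, pixel_size_um=None,
               frame_interval_min=None, meta_path=None) -> TrackedTissueMovie:
    """Read a movie written by :func:`write_movie` (lossless round trip)."""
    if meta_path is not None:
        meta = json.loads(Path(meta_path).read_text())
        pixel_size_um = pixel_size_um or meta["pixel_size_um"]
        frame_interval_min = frame_interval_min or meta["frame_interval_min"]
    if pixel_size_um is None:
        raise ValueError("pixel_size_um required (directly or via meta_path)")
    stack = tifffile.imread(str(tiff_path))
    if stack.ndim == 2:
        stack = stack[None]
    tracks = pd.read_csv(tracks_path)
    return TrackedTissueMovie(
        frames=[stack[i] for i in range(stack.shape[0])],
        pixel_size_um=float(pixel_size_um),
        tracks=tracks,
        frame_interval_min=float(frame_interval_min or 10.0),
    )


def write_annotation(annotation: OmmatidiumAnnotation, path) -> None:
    Path(path).write_text(json.dumps({
        "roles": {str(k): v for k, v in annotation.roles.items()},
        "furrow_axis_deg": annotation.furrow_axis_deg,
        "r7_frame": annotation.r7_frame,
        "r16_frame": annotation.r16_frame,
        "chirality": annotation.chirality,
        "first_level_ics": sorted(annotation.first_level_ics),
    }, indent=1))


def read_annotation(path) -> OmmatidiumAnnotation:
    d = json.loads(Path(path).read_text())
    return OmmatidiumAnnotation(
        roles={int(k): v for k, v in d["roles"].items()},
        furrow_axis_deg=float(d.get("furrow_axis_deg", 90.0)),
        r7_frame=d.get("r7_frame", "unknown"),
        r16_frame=d.get("r16_frame", "unknown"),
        chirality=d.get("chirality", "counterclockwise"),
        first_level_ics=frozenset(d.get("first_level_ics", ())),
    )


# ---------------------------------------------------------------------------
# cell-graph extraction


def _adjacency_from_labels(img: np.ndarray) -> set[tuple[int, int]]:
    """Label pairs sharing >= 1 boundary pixel-edge (4-connectivity)."""
    pairs: set[tuple[int, int]] = set()
    for a, b in ((img[:, :-1], img[:, 1:]), (img[:-1, :], img[1:, :])):
        diff = (a != b) & (a > 0) & (b > 0)
        if diff.any():
            av, bv = a[diff].astype(int), b[diff].astype(int)
            lo, hi = np.minimum(av, bv), np.maximum(av, bv)
            pairs.update(zip(lo.tolist(), hi.tolist()))
    return pairs


def _cell_polygon(mask: np.ndarray, origin_rc: tuple[int, int], px: float) -> Polygon:
    """Sub-pixel boundary polygon of a padded binary crop, in um."""
    contours = measure.find_contours(np.pad(mask, 1).astype(float), 0.5)
    poly = None
    for c in contours:
        # (row, col) -> (x, y) um; undo the 1-px pad
        xy = np.column_stack([
            (c[:, 1] - 1 + origin_rc[1]) * px,
            (c[:, 0] - 1 + origin_rc[0]) * px,
        ])
        p = Polygon(xy)
        if poly is None or p.area > poly.area:
            poly = p
    return poly


def build_cell_graph(movie: TrackedTissueMovie, frame: int) -> FrameGeometry:
    """Extract per-cell geometry and the neighbor graph of one frame.

    Boundaries are traced as sub-pixel contours between cell and non-cell
    pixels (reducing pixelation bias relative to pixel-edge counting);
    areas and perimeters come from the traced polygon. Cells touching the
    image border are flagged. Keys are persistent cell ids from the
    tracking table. An empty frame yields an empty geometry.
    """
    if not (0 <= frame < movie.n_frames):
        raise IndexError(f"frame {frame} out of range")
    img = movie.frames[frame]
    mapping = movie.label_to_cell(frame)
    geom = FrameGeometry()
    if img.max() == 0:
        import warnings

        warnings.warn(f"frame {frame} contains no labeled cells", stacklevel=2)
        return geom
    px = movie.pixel_size_um
    border_labels = set(np.unique(np.concatenate([
        img[0], img[-1], img[:, 0], img[:, -1]
    ]))) - {0}
    adj_labels = _adjacency_from_labels(img)
    neighbors: dict[int, set[int]] = {}
    for a, b in adj_labels:
        if a in mapping and b in mapping:
            neighbors.setdefault(mapping[a], set()).add(mapping[b])
            neighbors.setdefault(mapping[b], set()).add(mapping[a])
    for prop in measure.regionprops(img):
        label = int(prop.label)
        if label not in mapping:
            continue
        cid = mapping[label]
        sl = prop.slice
        mask = img[sl] == label
        poly = _cell_polygon(mask, (sl[0].start, sl[1].start), px)
        centroid = np.array(poly.centroid.coords[0])
        # marching-squares contours staircase along straight cell edges;
        # a one-pixel simplification recovers the underlying edge length
        simplified = poly.simplify(px)
        perimeter = float(simplified.length) if simplified.length > 0 else float(poly.length)
        geom.cells[cid] = CellGeometry(
            cell_id=cid,
            polygon_um=np.asarray(poly.exterior.coords),
            area_um2=float(poly.area),
            perimeter_um=perimeter,
            centroid_um=centroid,
            neighbors=frozenset(neighbors.get(cid, set())),
            on_border=label in border_labels,
        )
    geom.validate()
    return geom


# ---------------------------------------------------------------------------
# cell-graph sequences (abstract per-frame adjacency graphs)


@dataclass
class CellGraphSequence:
    """Per-frame adjacency graphs with persistent cell ids and lineage.

    Node attributes: ``area`` (um^2) and optionally ``centroid`` (um).
    ``lineage`` maps cell_id -> parent cell_id (None for founders).
    """

    graphs: list[nx.Graph]
    lineage: dict[int, int | None] = field(default_factory=dict)
    frame_interval_min: float = 10.0
    ommatidium: int = 0

    @property
    def n_frames(self) -> int:
        return len(self.graphs)

    def to_json(self, path) -> None:
        frames = []
        for g in self.graphs:
            frames.append({
                "nodes": [
                    {"cell_id": int(n), **{k: v for k, v in d.items()}}
                    for n, d in g.nodes(data=True)
                ],
                "edges": [[int(a), int(b)] for a, b in g.edges()],
            })
        Path(path).write_text(json.dumps({
            "frame_interval_min": self.frame_interval_min,
            "ommatidium": self.ommatidium,
            "lineage": {str(k): v for k, v in self.lineage.items()},
            "frames": frames,
        }))

    @classmethod
    def from_json(cls, path) -> "CellGraphSequence":
        d = json.loads(Path(path).read_text())
        graphs = []
        for fr in d["frames"]:
            g = nx.Graph()
            for node in fr["nodes"]:
                attrs = dict(node)
                cid = attrs.pop("cell_id")
                g.add_node(int(cid), **attrs)
            g.add_edges_from((int(a), int(b)) for a, b in fr["edges"])
            graphs.append(g)
        lineage = {int(k): (None if v is None else int(v))
                   for k, v in d.get("lineage", {}).items()}
        return cls(graphs, lineage, float(d.get("frame_interval_min", 10.0)),
                   int(d.get("ommatidium", 0)))


def movie_to_graph_sequence(movie: TrackedTissueMovie) -> CellGraphSequence:
    """Build the per-frame adjacency graph sequence of a tracked movie."""
    graphs = []
    for f in range(movie.n_frames):
        geom = build_cell_graph(movie, f)
        g = nx.Graph()
        for cid, cell in geom.cells.items():
            g.add_node(cid, area=cell.area_um2,
                       centroid=tuple(np.round(cell.centroid_um, 6)),
                       on_border=cell.on_border)
        g.add_edges_from(geom.adjacency)
        graphs.append(g)
    return CellGraphSequence(graphs, movie.lineage, movie.frame_interval_min)
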