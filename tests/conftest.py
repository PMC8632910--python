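"""Shared fixtures: synthetic movies, ledgers, and tiny hand-built movies."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from omtrack.io import OmmatidiumAnnotation, TrackedTissueMovie
from omtrack.presets import GOF, LOF, WILD_TYPE
from omtrack.synthetic import generate_event_ledger, generate_tissue_movie


@pytest.fixture(scope="session")
def wt_movie():
    """A moderate wild-type movie shared by round-trip and geometry tests."""
    return generate_tissue_movie(WILD_TYPE, n_frames=21, seed=42)


@pytest.fixture(scope="session")
def fluidity_movies():
    """LOF and GOF movies at a shared seed for monotonicity comparisons."""
    lof = generate_tissue_movie(LOF, n_frames=17, seed=7)
    gof = generate_tissue_movie(GOF, n_frames=17, seed=7)
    return {"lof": lof, "gof": gof}


@pytest.fixture(scope="session")
def wt_ledger():
    return generate_event_ledger(WILD_TYPE, n_frames=51, n_ommatidia=3, seed=42)


def make_movie(frames, pixel_size_um=0.1, tracks=None, frame_interval_min=10.0):
    """Assemble a movie from label arrays; identity tracks by default."""
    if tracks is None:
        rows = []
        for f, img in enumerate(frames):
            for lab in np.unique(img):
                if lab:
                    rows.append({"frame": f, "label": int(lab),
                                 "cell_id": int(lab), "parent_id": -1})
        tracks = pd.DataFrame(rows)
    return TrackedTissueMovie(frames=[np.asarray(f, dtype=np.uint16) for f in frames],
                              pixel_size_um=pixel_size_um, tracks=tracks,
                              frame_interval_min=frame_interval_min)


def blob_movie(positions_per_frame, shape=(60, 60), radius=3, pixel_size_um=0.1):
    """Movie of small square blobs centred at the given pixel positions.

    ``positions_per_frame``: list of dicts label -> (row, col).
    """
    frames = []
    for pos in positions_per_frame:
        img = np.zeros(shape, dtype=np.uint16)
        for lab, (r, c) in pos.items():
            r, c = int(round(r)), int(round(c))
            img[max(r - radius, 0):r + radius + 1,
                max(c - radius, 0):c + radius + 1] = lab
        frames.append(img)
    return make_movie(frames, pixel_size_um=pixel_size_um)


@pytest.fixture
def two_cell_annotation():
    return OmmatidiumAnnotation(
        roles={1: "R2", 2: "R5"}, furrow_axis_deg=90.0,
        r7_frame=0, r16_frame=0, chirality="counterclockwise",
    )
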