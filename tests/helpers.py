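"""Shared scene constructors for the tests.

The disk scenes give every object an exact shapely geometry alongside its
raster rendering, so pixel-based operators can be checked against exact
geometric oracles. Disks are sampled non-overlapping (gap ≥ 1 μm): somata do
not interpenetrate, and a pair of overlapping disks would rasterize into a
single object, which is a different scene, not an operator discrepancy.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Point

from astrospat.detection import segment_channel
from astrospat.spatial import PointPattern
from astrospat.synthetic import render_disks


def sample_disk_scene(
    rng: np.random.Generator,
    n_disks: int,
    window: tuple[float, float] = (300.0, 300.0),
    radius_range: tuple[float, float] = (3.0, 8.0),
    min_gap_um: float = 1.0,
    pixel_size_um: float = 0.5,
):
    """Non-overlapping random disks; returns (centers, radii, shapes, seg)."""
    w, h = window
    centers: list[np.ndarray] = []
    radii: list[float] = []
    margin = radius_range[1] + 2
    while len(centers) < n_disks:
        c = rng.uniform((margin, margin), (w - margin, h - margin))
        r = rng.uniform(*radius_range)
        if all(
            np.hypot(*(c - c2)) >= r + r2 + min_gap_um
            for c2, r2 in zip(centers, radii)
        ):
            centers.append(c)
            radii.append(r)
    centers_arr = np.array(centers)
    img = np.zeros(
        (round(h / pixel_size_um), round(w / pixel_size_um)), dtype=np.uint8
    )
    for c, r in zip(centers, radii):
        img |= render_disks(PointPattern(c[None, :], window), r, pixel_size_um)
    seg = segment_channel(img, 128, 0.0, pixel_size_um, "disks")
    shapes = {
        i + 1: Point(*c).buffer(r, quad_segs=64)
        for i, (c, r) in enumerate(zip(centers, radii))
    }
    return centers_arr, np.array(radii), shapes, seg


def match_disks_to_objects(centers, seg):
    """Label of the segmented object under each disk center."""
    px = seg.pixel_size_um
    lm = seg.label_mask
    cols = (centers[:, 0] / px).astype(int)
    rows = (centers[:, 1] / px).astype(int)
    return lm[rows, cols]


def comembership_mismatches(det_part: dict, orc_part: dict, shapes: dict):
    """Pairs whose clustered-together status differs, with their exact gaps."""
    ids = sorted(shapes)
    out = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            da, db = ids[a], ids[b]
            same_det = det_part.get(da, 0) != 0 and det_part.get(da) == det_part.get(db)
            same_orc = orc_part.get(da, 0) != 0 and orc_part.get(da) == orc_part.get(db)
            if same_det != same_orc:
                out.append((da, db, shapes[da].distance(shapes[db])))
    return out


def detected_partition(cluster_set, disk_labels):
    """Map disk id -> detected cluster id (0 = unclustered) via its object label."""
    obj2cluster: dict[int, int] = {}
    for cid, mids in cluster_set.members.items():
        for m in mids:
            obj2cluster[m] = cid
    return {
        i + 1: obj2cluster.get(int(lab), 0) for i, lab in enumerate(disk_labels)
    }


def oracle_partition(clusters):
    """Map disk id -> oracle cluster id (unclustered ids absent)."""
    out: dict[int, int] = {}
    for k, grp in enumerate(clusters):
        for d in grp:
            out[d] = k + 1
    return out
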