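"""Object detection on 8-bit channels: thresholding, counting, colocalization.

Mirrors the fixed-threshold ImageJ workflow the measurements were designed
around: a channel is binarized at a fixed 8-bit gray level (70 for the
astrocyte marker, 30 for puncta), 8-connected components become objects, and
objects carry intensity-weighted centroids and areas in μm². Cell counting is
frame-area-normalized (counts per 0.4 mm² by convention) and cells on the
image border are included. Dual-marker colocalization is scored by one-to-one
greedy centroid pairing within a distance budget (default 5 μm, about one soma
radius) — the original workflow scores this by eye; the explicit rule makes it
reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.feature import peak_local_max
from skimage.measure import label as _cc_label
from skimage.measure import regionprops_table

__all__ = [
    "SegmentationResult",
    "CellRecord",
    "ColocalizationResult",
    "PunctaCompartmentResult",
    "segment_channel",
    "max_project",
    "cells_from_segmentation",
    "detect_cell_centers",
    "read_cell_centers_csv",
    "count_cells_per_frame",
    "colocalize",
    "count_puncta",
]

#: default minimum object sizes (μm²): somata vs. puncta
MIN_AREA_SOMA_UM2 = 20.0
MIN_AREA_PUNCTUM_UM2 = 0.2


@dataclass(frozen=True)
class SegmentationResult:
    """Labeled objects of one channel at one threshold.

    ``objects`` is a DataFrame with columns
    ``id, x_um, y_um, area_um2, mean_intensity`` (centroids intensity-weighted,
    pixel-center convention); labels in ``label_mask`` are consecutive positive
    integers matching ``id``.
    """

    channel_name: str
    threshold: int
    label_mask: np.ndarray
    objects: pd.DataFrame
    pixel_size_um: float

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    @property
    def mask(self) -> np.ndarray:
        return self.label_mask > 0

    @property
    def total_area_um2(self) -> float:
        return float(self.objects["area_um2"].sum())

    def centroids_um(self) -> np.ndarray:
        return self.objects[["x_um", "y_um"]].to_numpy()


@dataclass(frozen=True)
class CellRecord:
    id: int
    marker: str
    centroid_um: tuple[float, float]
    region_label: str | None = None
    on_border: bool = False


@dataclass(frozen=True)
class ColocalizationResult:
    n_marker_a: int
    n_marker_b: int
    pairing: tuple[tuple[int, int], ...]
    n_dual: int = field(init=False)
    pct_a_also_b: float = field(init=False)
    pct_b_also_a: float = field(init=False)

    def __post_init__(self) -> None:
        nd = len(self.pairing)
        object.__setattr__(self, "n_dual", nd)
        object.__setattr__(
            self, "pct_a_also_b", 100.0 * nd / self.n_marker_a if self.n_marker_a else 0.0
        )
        object.__setattr__(
            self, "pct_b_also_a", 100.0 * nd / self.n_marker_b if self.n_marker_b else 0.0
        )


@dataclass(frozen=True)
class PunctaCompartmentResult:
    """Punctum counts and densities inside vs. outside a compartment mask."""

    n_inside: int
    n_outside: int
    area_inside_um2: float
    area_outside_um2: float
    density_inside: float
    density_outside: float
    flagged: bool = False

    @property
    def density_ratio(self) -> float:
        if self.density_outside and np.isfinite(self.density_outside):
            return self.density_inside / self.density_outside
        return np.nan


def max_project(stack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum-intensity projection of a z-stack.

    A single 2D plane (or a stack with one plane) is returned unchanged.
    """
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return stack
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError(f"expected a 2D image or non-empty 3D stack, got shape {stack.shape}")
    return stack.max(axis=0)


def segment_channel(
    image: np.ndarray,
    threshold: int,
    min_area_um2: float = 0.0,
    pixel_size_um: float = 1.0,
    channel_name: str = "",
) -> SegmentationResult:
    """Threshold an 8-bit channel and label 8-connected components.

    The binary mask is ``image >= threshold`` (the ImageJ "threshold to T and
    255, dark background" convention). Components smaller than
    ``min_area_um2`` are dropped and the survivors relabeled consecutively in
    scan order.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D image (max-project stacks first), got ndim={image.ndim}")
    if image.dtype != np.uint8:
        if np.issubdtype(image.dtype, np.integer) and image.min() >= 0 and image.max() <= 255:
            image = image.astype(np.uint8)
        else:
            raise ValueError(f"expected 8-bit input, got dtype {image.dtype}")
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {threshold}")
    if min_area_um2 < 0:
        raise ValueError(f"min_area_um2 must be >= 0, got {min_area_um2}")

    labels = _cc_label(image >= threshold, connectivity=2)
    px_area = pixel_size_um**2
    if labels.max() == 0:
        objects = pd.DataFrame(columns=["id", "x_um", "y_um", "area_um2", "mean_intensity"])
        return SegmentationResult(channel_name, threshold, labels, objects, pixel_size_um)

    props = regionprops_table(
        labels,
        intensity_image=image,
        properties=("label", "area", "centroid_weighted", "intensity_mean"),
    )
    df = pd.DataFrame(props)
    df["area_um2"] = df["area"] * px_area
    keep = df["area_um2"] >= min_area_um2
    df = df[keep].reset_index(drop=True)

    # relabel consecutively; dropped components become background
    relabel = np.zeros(labels.max() + 1, dtype=labels.dtype)
    relabel[df["label"].to_numpy()] = np.arange(1, len(df) + 1)
    labels = relabel[labels]

    objects = pd.DataFrame(
        {
            "id": np.arange(1, len(df) + 1),
            "x_um": (df["centroid_weighted-1"] + 0.5) * pixel_size_um,
            "y_um": (df["centroid_weighted-0"] + 0.5) * pixel_size_um,
            "area_um2": df["area_um2"].to_numpy(),
            "mean_intensity": df["intensity_mean"].to_numpy(),
        }
    )
    return SegmentationResult(channel_name, threshold, labels, objects, pixel_size_um)


def cells_from_segmentation(seg: SegmentationResult, marker: str) -> list[CellRecord]:
    """Turn segmented objects into cell records, flagging border objects.

    Substitute for manual center-dot placement: the intensity-weighted centroid
    stands in for the hand-placed soma dot. Border cells are flagged but
    retained (they are counted).
    """
    ny, nx = seg.label_mask.shape
    border_labels = set(np.unique(seg.label_mask[0, :])) | set(
        np.unique(seg.label_mask[-1, :])
    ) | set(np.unique(seg.label_mask[:, 0])) | set(np.unique(seg.label_mask[:, -1]))
    return [
        CellRecord(
            id=int(r.id),
            marker=marker,
            centroid_um=(float(r.x_um), float(r.y_um)),
            on_border=int(r.id) in border_labels,
        )
        for r in seg.objects.itertuples()
    ]


def detect_cell_centers(
    image: np.ndarray,
    marker: str = "",
    threshold: int = 70,
    min_distance_um: float = 4.0,
    pixel_size_um: float = 1.0,
    smooth_sigma_um: float = 1.0,
) -> list[CellRecord]:
    """Soma centers as local intensity maxima — the center-dot surrogate.

    The original counting/NND workflow marks one dot per soma by eye; touching
    somata are still resolved as two dots, which connected-component centroids
    cannot do. This surrogate places a dot at every local maximum above
    ``threshold`` after light smoothing, with maxima closer than
    ``min_distance_um`` (about one soma-core radius pair) merged into one.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D image, got ndim={image.ndim}")
    if smooth_sigma_um > 0:
        image = gaussian_filter(image, smooth_sigma_um / pixel_size_um)
    peaks = peak_local_max(
        image,
        min_distance=max(1, int(round(min_distance_um / pixel_size_um))),
        threshold_abs=float(threshold),
        exclude_border=False,
    )
    ny, nx = image.shape
    return [
        CellRecord(
            id=i + 1,
            marker=marker,
            centroid_um=((c + 0.5) * pixel_size_um, (r + 0.5) * pixel_size_um),
            on_border=r in (0, ny - 1) or c in (0, nx - 1),
        )
        for i, (r, c) in enumerate(peaks)
    ]


def read_cell_centers_csv(path: str | Path, marker: str | None = None) -> list[CellRecord]:
    """Import externally provided cell centers (columns ``x_um, y_um[, marker]``).

    Keeps manually scored workflows reproducible through the same code path.
    """
    df = pd.read_csv(path)
    if marker is not None and "marker" in df.columns:
        df = df[df["marker"] == marker]
    return [
        CellRecord(
            id=i + 1,
            marker=marker or str(getattr(r, "marker", "")),
            centroid_um=(float(r.x_um), float(r.y_um)),
        )
        for i, r in enumerate(df.itertuples())
    ]


def count_cells_per_frame(
    cells: list[CellRecord] | int,
    frame_area_mm2: float,
    reference_area_mm2: float = 0.4,
) -> tuple[int, float]:
    """Raw cell count and count normalized to a reference frame area.

    Border cells are included. ``reference_area_mm2`` defaults to the 0.4 mm²
    epifluorescence counting frame; confocal frames use 0.34 mm².
    """
    if frame_area_mm2 <= 0:
        raise ValueError(f"frame_area_mm2 must be > 0, got {frame_area_mm2}")
    n = cells if isinstance(cells, int) else len(cells)
    return n, n * (reference_area_mm2 / frame_area_mm2)


def colocalize(
    cells_a: list[CellRecord],
    cells_b: list[CellRecord],
    max_pairing_dist_um: float = 5.0,
) -> ColocalizationResult:
    """One-to-one greedy centroid pairing between two marker channels.

    Candidate pairs within ``max_pairing_dist_um`` are taken in ascending
    distance order (ties broken by lexicographic (a_id, b_id)); each object is
    used at most once. The result's percentages are the dual fraction of each
    channel.
    """
    if max_pairing_dist_um < 0:
        raise ValueError(f"max_pairing_dist_um must be >= 0, got {max_pairing_dist_um}")
    pa = np.array([c.centroid_um for c in cells_a], dtype=float).reshape(-1, 2)
    pb = np.array([c.centroid_um for c in cells_b], dtype=float).reshape(-1, 2)
    ids_a = [c.id for c in cells_a]
    ids_b = [c.id for c in cells_b]
    cand = []
    if len(pa) and len(pb):
        d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
        ii, jj = np.nonzero(d <= max_pairing_dist_um)
        cand = sorted(
            (float(d[i, j]), ids_a[i], ids_b[j], i, j) for i, j in zip(ii, jj)
        )
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairing = []
    for _dist, aid, bid, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairing.append((aid, bid))
    return ColocalizationResult(
        n_marker_a=len(pa), n_marker_b=len(pb), pairing=tuple(pairing)
    )


def count_puncta(
    puncta_seg: SegmentationResult,
    compartment_mask: np.ndarray,
    compartment_area_um2: float | None = None,
    frame_area_um2: float | None = None,
) -> PunctaCompartmentResult:
    """Split punctum counts by compartment and convert to densities.

    A punctum is inside iff its centroid pixel lies on the mask (the analogue
    of ImageJ Clear / Clear Outside, which removes particles by location);
    inside + outside always equals the total. Outside density uses
    frame area − compartment area. A zero-area compartment with a nonzero
    count is flagged and its density reported as NaN.
    """
    mask = np.asarray(compartment_mask, dtype=bool)
    if mask.shape != puncta_seg.label_mask.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match segmentation frame "
            f"{puncta_seg.label_mask.shape}"
        )
    px = puncta_seg.pixel_size_um
    if compartment_area_um2 is None:
        compartment_area_um2 = float(mask.sum()) * px**2
    if frame_area_um2 is None:
        frame_area_um2 = mask.size * px**2

    cent = puncta_seg.centroids_um()
    if len(cent):
        col = np.clip((cent[:, 0] / px).astype(int), 0, mask.shape[1] - 1)
        row = np.clip((cent[:, 1] / px).astype(int), 0, mask.shape[0] - 1)
        inside = mask[row, col]
        n_in = int(inside.sum())
    else:
        n_in = 0
    n_out = puncta_seg.n_objects - n_in

    area_out = frame_area_um2 - compartment_area_um2
    flagged = False
    if compartment_area_um2 > 0:
        dens_in = n_in / compartment_area_um2
    else:
        dens_in = np.nan
        if n_in:
            flagged = True
            warnings.warn("puncta inside a zero-area compartment; density undefined", stacklevel=2)
    if area_out > 0:
        dens_out = n_out / area_out
    else:
        dens_out = np.nan
        if n_out:
            flagged = True
            warnings.warn("puncta outside with zero outside area; density undefined", stacklevel=2)
    return PunctaCompartmentResult(
        n_inside=n_in,
        n_outside=n_out,
        area_inside_um2=compartment_area_um2,
        area_outside_um2=area_out,
        density_inside=dens_in,
        density_outside=dens_out,
        flagged=flagged,
    )
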