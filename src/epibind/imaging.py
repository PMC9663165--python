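"""Fluorescence-image scoring for dendrite morphology and synapse density.

Implements the MAP2 continuity score (percent of a traced dendritic path
with above-threshold MAP2 signal on a thresholded 8-bit image), synaptic
puncta detection and per-µm density along annotated dendrite paths,
selection of paths in contact with a ligand-presenting cell mask, and
spine-density summaries from Golgi count tables.

Dendrite paths are polylines of (x, y) pixel vertices (0-based, y down),
traced externally; automatic tracing is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString, Point
from skimage import filters, measure, restoration

__all__ = [
    "ContinuityScore",
    "PunctaRecord",
    "DensityRecord",
    "path_length",
    "subtract_background",
    "threshold_channel",
    "sample_profile",
    "map2_continuity",
    "detect_puncta",
    "puncta_density",
    "contact_paths",
    "spine_density",
    "normalize_to_8bit",
]


def path_length(path: np.ndarray) -> float:
    """Polyline arc length in pixels."""
    path = np.asarray(path, dtype=float)
    if path.ndim != 2 or path.shape[0] < 2 or path.shape[1] != 2:
        raise ValueError("path must be an (n>=2, 2) array of (x, y) vertices")
    return float(np.sum(np.hypot(*np.diff(path, axis=0).T)))


def normalize_to_8bit(channel: np.ndarray) -> np.ndarray:
    """Return an 8-bit view of a channel, min-max rescaling if needed."""
    channel = np.asarray(channel)
    if channel.dtype == np.uint8:
        return channel
    warnings.warn("rescaling non-8-bit channel to uint8 (min-max)",
                  stacklevel=2)
    lo, hi = float(channel.min()), float(channel.max())
    if hi == lo:
        return np.zeros(channel.shape, dtype=np.uint8)
    return np.round(255.0 * (channel - lo) / (hi - lo)).astype(np.uint8)


def subtract_background(channel: np.ndarray, radius: int = 50) -> np.ndarray:
    """Rolling-ball background subtraction; result is non-negative."""
    if radius <= 0:
        raise ValueError("rolling-ball radius must be > 0")
    channel = np.asarray(channel, dtype=float)
    bg = restoration.rolling_ball(channel, radius=radius)
    return np.clip(channel - bg, 0, None)


def threshold_channel(channel: np.ndarray, method: str | int = "otsu",
                      ) -> np.ndarray:
    """Binarize an 8-bit channel to {0, 255}.

    Pixels strictly above the threshold map to 255 (so dividing the profile
    by 255 gives an on/off indicator); a pixel exactly at the threshold is
    off.  ``method`` is ``"otsu"`` or a fixed integer threshold.  Otsu on a
    constant image is undefined and raises, prompting a fixed threshold.
    """
    channel = np.asarray(channel)
    if method == "otsu":
        if channel.min() == channel.max():
            raise ValueError(
                "Otsu threshold undefined on a constant image; "
                "use a fixed threshold")
        thr = filters.threshold_otsu(channel)
    else:
        thr = float(method)
    return np.where(channel > thr, 255, 0).astype(np.uint8)


def sample_profile(image: np.ndarray, path: np.ndarray) -> np.ndarray:
    """Intensity profile along a polyline at unit (1-pixel) spacing.

    Samples ``round(arc length) + 1`` points uniformly along the path and
    reads the nearest pixel at each (exact on binary images).  Raises if
    any vertex falls outside the image.
    """
    path = np.asarray(path, dtype=float)
    h, w = image.shape[:2]
    for i, (x, y) in enumerate(path):
        if not (0 <= round(x) < w and 0 <= round(y) < h):
            raise ValueError(f"path vertex {i} at ({x}, {y}) is outside "
                             f"the {w}x{h} image")
    total = path_length(path)
    n_samples = int(round(total)) + 1
    seg = np.hypot(*np.diff(path, axis=0).T)
    cum = np.concatenate(([0.0], np.cumsum(seg)))
    t = np.linspace(0.0, total, n_samples)
    xs = np.interp(t, cum, path[:, 0])
    ys = np.interp(t, cum, path[:, 1])
    rows = np.clip(np.round(ys).astype(int), 0, h - 1)
    cols = np.clip(np.round(xs).astype(int), 0, w - 1)
    return np.asarray(image[rows, cols], dtype=float)


@dataclass(frozen=True)
class ContinuityScore:
    """MAP2 continuity of one dendrite path.

    ``score`` = 100 x (profile area under the curve) / (255 x path length
    in samples) on a {0,255} thresholded image — i.e. the percent of the
    traced path carrying MAP2 signal.
    """

    path_id: int
    score: float
    auc: float
    n_samples: int
    length_um: float


def map2_continuity(profile: np.ndarray, path_id: int = 0,
                    pixel_size_um: float = 1.0) -> ContinuityScore:
    """Continuity score from a thresholded-MAP2 profile.

    C = 100 * sum(profile) / (255 * n_samples); on a {0,255} profile this
    equals the percentage of samples that are on.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size == 0:
        raise ValueError("profile is empty")
    auc = float(profile.sum())
    n = profile.size
    score = 100.0 * auc / (255.0 * n)
    return ContinuityScore(path_id=path_id, score=score, auc=auc,
                           n_samples=n, length_um=(n - 1) * pixel_size_um)


@dataclass(frozen=True)
class PunctaRecord:
    centroid: tuple[float, float]   # (x, y) pixels
    area: int                       # pixels²


def detect_puncta(binary: np.ndarray, min_area: int = 2,
                  max_area: int = 200) -> list[PunctaRecord]:
    """Connected-component puncta (8-connectivity) with area in
    [min_area, max_area]."""
    if min_area > max_area:
        raise ValueError("min_area must not exceed max_area")
    labels = measure.label(np.asarray(binary) > 0, connectivity=2)
    out = []
    for region in measure.regionprops(labels):
        if min_area <= region.area <= max_area:
            cy, cx = region.centroid
            out.append(PunctaRecord(centroid=(float(cx), float(cy)),
                                    area=int(region.area)))
    return out


@dataclass(frozen=True)
class DensityRecord:
    path_id: int
    marker: str
    count: int
    length_um: float
    density_per_um: float


def puncta_density(puncta, path: np.ndarray, pixel_size_um: float,
                   max_lateral_um: float = 1.0, marker: str = "",
                   path_id: int = 0) -> DensityRecord:
    """Density of puncta assigned to a dendrite path, per µm.

    A punctum belongs to the path when its centroid lies within
    ``max_lateral_um`` (inclusive) of the polyline.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    length_um = path_length(path) * pixel_size_um
    line = LineString(np.asarray(path, dtype=float))
    max_px = max_lateral_um / pixel_size_um
    count = sum(1 for p in puncta
                if line.distance(Point(p.centroid)) <= max_px + 1e-9)
    return DensityRecord(path_id=path_id, marker=marker, count=count,
                         length_um=length_um,
                         density_per_um=count / length_um)


def contact_paths(paths, cell_mask: np.ndarray, pixel_size_um: float,
                  dilation_um: float = 0.0) -> set[int]:
    """Indices of paths in contact with a (dilated) cell mask.

    A path is "in contact" when any of its unit-spaced samples lies within
    ``dilation_um`` of the mask (boundary inclusive; distance-transform
    rule).  An empty mask yields no contacts with a warning.
    """
    cell_mask = np.asarray(cell_mask) > 0
    if not cell_mask.any():
        warnings.warn("empty cell mask: no paths can be in contact",
                      stacklevel=2)
        return set()
    dist = ndimage.distance_transform_edt(~cell_mask)
    radius_px = dilation_um / pixel_size_um
    in_contact = set()
    for i, path in enumerate(paths):
        d = sample_profile(dist, np.asarray(path, dtype=float))
        if (d <= radius_px + 1e-9).any():
            in_contact.add(i)
    return in_contact


def spine_density(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-neuron spine densities and per-group summaries.

    ``table`` has columns ``group``, ``neuron_id``, ``count``,
    ``length_um``.  Returns ``(per_neuron, per_group)`` where per-neuron
    adds ``density_per_um`` and the group table has mean, SEM and n.
    """
    if (table["length_um"] <= 0).any():
        raise ValueError("segment lengths must be > 0")
    if (table["count"] < 0).any():
        raise ValueError("spine counts must be >= 0")
    per_neuron = table.copy()
    per_neuron["density_per_um"] = per_neuron["count"] / per_neuron["length_um"]
    grp = per_neuron.groupby("group")["density_per_um"]
    per_group = pd.DataFrame({
        "mean": grp.mean(),
        "sem": grp.sem(),
        "n": grp.size(),
    }).reset_index()
    return per_neuron, per_group
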