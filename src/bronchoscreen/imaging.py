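"""Spheroid segmentation and per-spheroid / per-well feature extraction.

The segmenter is a deterministic classical pipeline: global Otsu threshold
on the live-dye channel, morphological hole filling (so dim lumens stay
inside their spheroid), 8-connected component labelling, and a minimum-area
filter. Any externally produced label map (e.g. from a learned segmenter)
can be passed straight to :func:`measure_spheroids`.

Mucin "active area" inside each spheroid is segmented with an Otsu
threshold computed *within* the spheroid mask, falling back to an absolute
threshold when the within-mask contrast is degenerate. The per-spheroid
mucin ratio is active area / spheroid area, a dimensionless number in
[0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as _cc_label
from skimage.measure import regionprops

DEFAULT_MUCIN_CHANNELS = ("muc5ac", "muc5b")


def segment_spheroids(
    image: np.ndarray,
    min_area: int = 50,
    expected_diameter: float | None = None,
) -> np.ndarray:
    """Segment spheroids in a single live-dye channel.

    Otsu threshold -> hole filling -> 8-connected components -> objects
    smaller than ``min_area`` pixels removed. Labels are renumbered
    1..n_objects; 0 is background. An all-constant image yields an empty
    label map rather than an error.

    ``expected_diameter`` (pixels), when given, sets a light Gaussian
    pre-smoothing scale (diameter / 20) that suppresses noise at the scale
    of the objects being segmented.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment_spheroids expects a single-channel 2D image")
    if min_area <= 0:
        raise ValueError("min_area must be positive")
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    if expected_diameter is not None and expected_diameter > 0:
        img = gaussian(img, sigma=expected_diameter / 20.0, preserve_range=True)
        if np.ptp(img) == 0:
            return np.zeros(img.shape, dtype=np.int32)
    mask = img > threshold_otsu(img)
    mask = ndi.binary_fill_holes(mask)
    labels = _cc_label(mask, connectivity=2)
    # area filter + sequential relabel
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= min_area)
    keep = keep[keep > 0]
    remap = np.zeros(counts.size, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    return remap[labels]


def _mucin_active(values: np.ndarray, fallback_abs: float | None) -> int:
    """Pixels above the within-mask Otsu threshold (absolute fallback)."""
    if values.size == 0:
        return 0
    if np.ptp(values) == 0:
        if fallback_abs is not None:
            return int(np.count_nonzero(values > fallback_abs))
        return 0
    try:
        thr = threshold_otsu(values)
    except ValueError:
        thr = fallback_abs if fallback_abs is not None else np.inf
    return int(np.count_nonzero(values > thr))


def measure_spheroids(
    labels: np.ndarray,
    channels: Mapping[str, np.ndarray],
    spheroid_channel: str = "spheroid",
    mucin_channels: Sequence[str] = DEFAULT_MUCIN_CHANNELS,
    mucin_fallback_abs: float | None = None,
) -> pd.DataFrame:
    """Per-spheroid features from a label map and a channel dictionary.

    Returns a DataFrame with one row per label: ``spheroid`` (label id),
    ``area`` (px), ``total_intensity`` (sum of the spheroid channel over
    the mask), ``centroid_row``/``centroid_col``, and per mucin channel
    ``<name>_active_area``, ``<name>_total_intensity`` and
    ``<name>_ratio`` = active area / area.
    """
    labels = np.asarray(labels)
    for name, ch in channels.items():
        if ch.shape != labels.shape:
            raise ValueError(f"channel {name!r} shape differs from label map")
    missing = [c for c in (spheroid_channel, *mucin_channels) if c not in channels]
    if missing:
        raise ValueError(f"missing channels: {missing}")

    rows = []
    for prop in regionprops(labels, intensity_image=channels[spheroid_channel]):
        mask = labels == prop.label
        row = {
            "spheroid": prop.label,
            "area": int(prop.area),
            "total_intensity": float(channels[spheroid_channel][mask].sum()),
            "centroid_row": prop.centroid[0],
            "centroid_col": prop.centroid[1],
        }
        for name in mucin_channels:
            vals = channels[name][mask]
            active = _mucin_active(vals, mucin_fallback_abs)
            row[f"{name}_active_area"] = active
            row[f"{name}_total_intensity"] = float(vals.sum())
            row[f"{name}_ratio"] = active / row["area"]
        rows.append(row)
    columns = [
        "spheroid",
        "area",
        "total_intensity",
        "centroid_row",
        "centroid_col",
    ] + [
        f"{name}_{suffix}"
        for name in mucin_channels
        for suffix in ("active_area", "total_intensity", "ratio")
    ]
    return pd.DataFrame(rows, columns=columns)


@dataclass
class WellMetadata:
    plate: str
    well: str
    role: str
    compound: str = ""
    concentration: float = float("nan")
    replicate: int = 0
    manual_exclusion: bool = False


def aggregate_well(
    records: pd.DataFrame,
    nuclear_channel: np.ndarray,
    labels: np.ndarray,
    metadata: WellMetadata,
    mucin_channels: Sequence[str] = DEFAULT_MUCIN_CHANNELS,
) -> dict:
    """Aggregate per-spheroid records to one well-level row.

    ``spheroid_count`` is the number of records, means are arithmetic means
    over the contributing spheroids, and ``total_nuclear_intensity`` sums
    the nuclear channel over the union of spheroid masks. A well with zero
    spheroids carries count 0 and NaN means.
    """
    n = len(records)
    row = {
        "plate": metadata.plate,
        "well": metadata.well,
        "role": metadata.role,
        "compound": metadata.compound,
        "concentration": metadata.concentration,
        "replicate": metadata.replicate,
        "spheroid_count": n,
        "mean_area": float(records["area"].mean()) if n else float("nan"),
        "total_nuclear_intensity": float(nuclear_channel[labels > 0].sum()),
        "manual_exclusion": metadata.manual_exclusion,
    }
    for name in mucin_channels:
        row[f"mean_{name}_ratio"] = (
            float(records[f"{name}_ratio"].mean()) if n else float("nan")
        )
    # primary screen readout alias: MUC5AC is the first mucin channel
    row["mean_mucin_ratio"] = row[f"mean_{mucin_channels[0]}_ratio"]
    return row


def quantify_well(
    stack: np.ndarray,
    metadata: WellMetadata,
    channel_names: Sequence[str] = ("spheroid", "muc5ac", "muc5b", "nuclear"),
    min_area: int = 50,
    expected_diameter: float | None = None,
    labels: np.ndarray | None = None,
    mucin_fallback_abs: float | None = None,
) -> tuple[dict, pd.DataFrame, np.ndarray]:
    """Segment, measure and aggregate one multi-channel well image.

    ``labels`` can be supplied to skip the built-in segmenter (e.g. an
    externally produced label map). Returns the well row, the per-spheroid
    table and the label map used.
    """
    if stack.ndim != 3 or stack.shape[0] != len(channel_names):
        raise ValueError(
            f"expected a stack of {len(channel_names)} channels, got "
            f"{stack.shape}"
        )
    channels = dict(zip(channel_names, stack))
    if labels is None:
        labels = segment_spheroids(
            channels["spheroid"], min_area=min_area,
            expected_diameter=expected_diameter,
        )
    mucins = [c for c in channel_names if c not in ("spheroid", "nuclear")]
    records = measure_spheroids(
        labels, channels, mucin_channels=mucins,
        mucin_fallback_abs=mucin_fallback_abs,
    )
    row = aggregate_well(
        records, channels["nuclear"], labels, metadata, mucin_channels=mucins
    )
    return row, records, labels
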