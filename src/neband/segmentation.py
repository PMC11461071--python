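"""Nucleus segmentation from the DNA stain and marker gating.

Nuclei ("DAPI objects") are segmented by smoothing + global threshold,
hole filling and a minimum-area filter, optionally splitting touching
blobs by seeded watershed on the distance transform.  Cells are then
gated for analysis by a nuclear differentiation marker (MyoG-like mean
intensity inside the nucleus) or by a cytoplasmic syncytial marker
(MHC-like overlap of the perinuclear band).

Conventions used throughout the package: coordinates are 0-based
(row, col); label maps are integer arrays with 0 = background; distances
are exact Euclidean distances between pixel centres.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_li, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

__all__ = [
    "segment_nuclei",
    "gate_nuclear_marker",
    "gate_cyto_marker",
    "expand_labels_nearest",
    "nearest_object_distance",
    "label_means",
]

_THRESHOLD_FUNCS = {"otsu": threshold_otsu, "li": threshold_li, "mean": np.mean}


def _resolve_threshold(image: np.ndarray, method) -> float:
    if isinstance(method, (int, float)) and not isinstance(method, bool):
        return float(method)
    try:
        return float(_THRESHOLD_FUNCS[method](image))
    except KeyError:
        raise ValueError(
            f"unknown threshold method {method!r}; use one of {sorted(_THRESHOLD_FUNCS)} "
            "or an absolute value"
        ) from None


def segment_nuclei(
    dapi: np.ndarray,
    min_area_px: int = 50,
    threshold_method="otsu",
    split_touching: bool = False,
    smooth_sigma: float = 1.0,
    split_min_distance: int = 5,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Segment nuclei from a DNA-stain channel.

    Parameters
    ----------
    dapi
        2D non-negative intensity raster.
    min_area_px
        Objects smaller than this are removed.
    threshold_method
        ``"otsu"`` (default), ``"li"``, ``"mean"`` or an absolute value.
    split_touching
        If True, separate merged blobs by seeded watershed on the
        Euclidean distance transform.
    smooth_sigma
        Gaussian pre-smoothing in pixels (0 disables).

    Returns
    -------
    labels : 2D int array, 0 = background
    nuclei : DataFrame with columns ``id, centroid_row, centroid_col,
        area_px, on_border`` (border-touching nuclei are flagged so band
        measurements, which would be truncated, can exclude them).
    """
    dapi = np.asarray(dapi, dtype=float)
    if dapi.size == 0:
        raise ValueError("empty image")
    empty = pd.DataFrame(
        columns=["id", "centroid_row", "centroid_col", "area_px", "on_border"]
    ).astype({"id": int, "area_px": int, "on_border": bool})

    smoothed = ndi.gaussian_filter(dapi, smooth_sigma) if smooth_sigma > 0 else dapi
    if not np.any(smoothed > 0):
        return np.zeros(dapi.shape, dtype=np.int32), empty
    if smoothed.max() == smoothed.min():  # constant non-zero image: no objects
        return np.zeros(dapi.shape, dtype=np.int32), empty

    mask = smoothed >= _resolve_threshold(smoothed, threshold_method)
    mask = ndi.binary_fill_holes(mask)

    if split_touching:
        distance = ndi.distance_transform_edt(mask)
        peaks = peak_local_max(
            distance, min_distance=split_min_distance, labels=mask, exclude_border=False
        )
        markers = np.zeros(mask.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-distance, markers, mask=mask)
    else:
        labels, _ = ndi.label(mask)
    labels = labels.astype(np.int32)

    # size filter, then relabel consecutively so ids match table rows
    rows = []
    out = np.zeros_like(labels)
    next_id = 1
    for prop in regionprops(labels):
        if prop.area < min_area_px:
            continue
        rr, cc = prop.coords[:, 0], prop.coords[:, 1]
        on_border = bool(
            (rr.min() == 0)
            or (cc.min() == 0)
            or (rr.max() == labels.shape[0] - 1)
            or (cc.max() == labels.shape[1] - 1)
        )
        out[rr, cc] = next_id
        rows.append(
            {
                "id": next_id,
                "centroid_row": prop.centroid[0],
                "centroid_col": prop.centroid[1],
                "area_px": int(prop.area),
                "on_border": on_border,
            }
        )
        next_id += 1
    nuclei = pd.DataFrame(rows) if rows else empty
    return out, nuclei


def label_means(labels: np.ndarray, channel: np.ndarray, ids=None) -> pd.Series:
    """Mean channel intensity within each labelled object."""
    labels = np.asarray(labels)
    channel = np.asarray(channel, dtype=float)
    if labels.shape != channel.shape:
        raise ValueError("labels and channel must be co-registered (same shape)")
    if ids is None:
        ids = np.unique(labels)
        ids = ids[ids > 0]
    ids = np.asarray(ids, dtype=int)
    means = ndi.mean(channel, labels=labels, index=ids) if len(ids) else []
    return pd.Series(means, index=pd.Index(ids, name="id"), name="mean")


def _otsu_exact(values: np.ndarray) -> float:
    """Exact discrete Otsu threshold for a small sample.

    Evaluates the between-class variance at every split of the sorted
    sample (no histogram binning, so it is exact and scale-invariant even
    for a handful of values) and returns the midpoint between the two
    classes at the best split.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    best_k, best_var = 1, -np.inf
    csum = np.cumsum(v)
    total = csum[-1]
    for k in range(1, n):
        w0 = k / n
        mu0 = csum[k - 1] / k
        mu1 = (total - csum[k - 1]) / (n - k)
        var = w0 * (1 - w0) * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_k = var, k
    return float((v[best_k - 1] + v[best_k]) / 2)


def gate_nuclear_marker(
    labels: np.ndarray, marker: np.ndarray, threshold="otsu-of-means"
) -> pd.DataFrame:
    """Gate nuclei by mean nuclear-marker intensity (MyoG-style).

    A nucleus is positive iff its mean marker intensity within the
    nucleus mask is >= the threshold.  ``threshold`` is an absolute
    intensity, or ``"otsu-of-means"`` to apply Otsu's criterion to the
    per-field vector of nuclear means (exact discrete form, since the
    vector holds only as many values as there are nuclei; scale-invariant;
    needs >= 2 nuclei).

    Returns a DataFrame indexed by nucleus id with columns
    ``mean_intensity`` and ``positive``.
    """
    means = label_means(labels, marker)
    if threshold == "otsu-of-means":
        if len(means) < 2:
            raise ValueError(
                "otsu-of-means gating needs at least 2 nuclei; "
                "pass an absolute threshold instead"
            )
        if means.max() == means.min():
            warnings.warn(
                "all nuclear means identical; otsu-of-means gating marks all positive",
                stacklevel=2,
            )
            thr = means.iloc[0]
        else:
            thr = _otsu_exact(means.to_numpy())
    else:
        thr = float(threshold)
    return pd.DataFrame(
        {"mean_intensity": means, "positive": means >= thr}, index=means.index
    )


def gate_cyto_marker(
    labels: np.ndarray,
    mhc: np.ndarray,
    band_width_px: int = 10,
    overlap_fraction: float = 0.5,
    threshold="otsu",
) -> pd.DataFrame:
    """Gate nuclei by overlap of their outward band with the MHC mask.

    The MHC channel is binarized (Otsu by default; pass a boolean mask to
    skip binarization).  A nucleus is positive iff >= ``overlap_fraction``
    of its outward band of width ``band_width_px`` lies inside the mask.
    """
    if band_width_px < 1:
        raise ValueError("band_width_px must be >= 1")
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    labels = np.asarray(labels)
    mhc = np.asarray(mhc)
    if mhc.dtype == bool:
        mask = mhc
    else:
        mhc = mhc.astype(float)
        mask = (
            mhc >= _resolve_threshold(mhc, threshold)
            if np.any(mhc > 0) and mhc.max() > mhc.min()
            else np.zeros_like(mhc, dtype=bool)
        )
    expanded = expand_labels_nearest(labels, band_width_px)
    band = np.where(labels == 0, expanded, 0)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    rows = []
    for i in ids:
        sel = band == i
        n = int(sel.sum())
        frac = float(mask[sel].sum() / n) if n else 0.0
        rows.append({"id": int(i), "band_overlap_fraction": frac, "positive": frac >= overlap_fraction})
    return pd.DataFrame(rows).set_index("id") if rows else pd.DataFrame(
        columns=["band_overlap_fraction", "positive"]
    )


def nearest_object_distance(labels: np.ndarray):
    """Per-pixel nearest object, its Euclidean distance, and a tie flag.

    For every pixel, the distance to each labelled object is the
    Euclidean distance to that object's nearest pixel centre.  Ties
    (two objects exactly equidistant) are resolved to the smaller label
    id and flagged.  Pixels inside an object get distance 0 and their
    own label.
    """
    labels = np.asarray(labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    best = np.full(labels.shape, np.inf)
    nearest = np.zeros(labels.shape, dtype=np.int32)
    tie = np.zeros(labels.shape, dtype=bool)
    for i in ids:  # ascending ids + strict '<' => ties stay with the smaller id
        d = ndi.distance_transform_edt(labels != i)
        equal = d == best
        closer = d < best
        tie[equal] = True
        tie[closer] = False
        nearest[closer] = i
        best[closer] = d[closer]
    return nearest, best, tie


def expand_labels_nearest(labels: np.ndarray, distance_px: float) -> np.ndarray:
    """Grow labels into the background by nearest-object Euclidean distance.

    Each background pixel within ``distance_px`` of any object takes the
    label of the nearest object; exact ties go to the smaller label id.
    Object pixels keep their labels.  ``distance_px = 0`` is the identity.
    """
    if distance_px < 0:
        raise ValueError("distance_px must be >= 0")
    labels = np.asarray(labels)
    if distance_px == 0 or labels.max() <= 0:
        return labels.copy()
    nearest, dist, _ = nearest_object_distance(labels)
    out = labels.copy()
    grow = (labels == 0) & (dist <= distance_px)
    out[grow] = nearest[grow]
    return out
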