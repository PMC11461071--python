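"""Myotube fusion index and fibre internuclear spacing.

The fusion index is the percentage of all nuclei in a field that reside
in MHC-positive syncytia containing at least two nuclei.  Fibre length
and internuclear spacing are computed from manually annotated polylines
and nucleus centroids: length is the polyline arc length, spacing the
arc-length distance between consecutive centroid projections, both in
micrometres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .io import DEFAULT_PIXEL_SIZE_UM

__all__ = [
    "FusionResult",
    "fusion_index",
    "FibreAnnotation",
    "SpacingResult",
    "internuclear_spacing",
    "read_fibre_annotations",
]


@dataclass
class FusionResult:
    n_nuclei_total: int
    n_nuclei_in_myotubes: int
    fusion_index_pct: float
    myotubes: pd.DataFrame  # columns: component_id, n_nuclei (components with >= min_nuclei)

    def __post_init__(self) -> None:
        if self.n_nuclei_total > 0:
            expected = 100.0 * self.n_nuclei_in_myotubes / self.n_nuclei_total
            if abs(self.fusion_index_pct - expected) > 1e-9:
                raise ValueError("fusion_index_pct inconsistent with counts")


def _binarize(mhc: np.ndarray, threshold) -> np.ndarray:
    mhc = np.asarray(mhc)
    if mhc.dtype == bool:
        return mhc
    mhc = mhc.astype(float)
    if not np.any(mhc > 0) or mhc.max() == mhc.min():
        return np.zeros_like(mhc, dtype=bool)
    if threshold == "otsu":
        t = float(threshold_otsu(mhc))
    else:
        t = float(threshold)
    return mhc >= t


def fusion_index(
    nuclei_labels: np.ndarray,
    mhc: np.ndarray,
    connectivity: int = 2,
    membership: str = "centroid",
    overlap_fraction: float = 0.5,
    min_nuclei: int = 2,
    threshold="otsu",
) -> FusionResult | None:
    """Fusion index of a field.

    Connected components of the binarized MHC mask are candidate
    myotubes.  A nucleus belongs to a component if its centroid pixel
    lies inside it (``membership="centroid"``, default) or if at least
    ``overlap_fraction`` of its area overlaps it (``membership="overlap"``).
    Components holding >= ``min_nuclei`` nuclei count as myotubes; the
    index is 100 x (nuclei in myotubes) / (total nuclei).

    Returns None with a warning when the field contains no nuclei.
    """
    if membership not in ("centroid", "overlap"):
        raise ValueError("membership must be 'centroid' or 'overlap'")
    nuclei_labels = np.asarray(nuclei_labels)
    mask = _binarize(mhc, threshold)
    if mask.shape != nuclei_labels.shape:
        raise ValueError("MHC mask and nucleus labels must be co-registered")

    props = regionprops(nuclei_labels)
    if not props:
        warnings.warn("no nuclei in field: fusion index reported absent", stacklevel=2)
        return None

    comps = cc_label(mask, connectivity=connectivity)
    assignment: dict[int, int] = {}
    for prop in props:
        if membership == "centroid":
            r, c = (int(round(x)) for x in prop.centroid)
            r = min(max(r, 0), comps.shape[0] - 1)
            c = min(max(c, 0), comps.shape[1] - 1)
            comp = int(comps[r, c])
        else:
            comp_ids, counts = np.unique(
                comps[prop.coords[:, 0], prop.coords[:, 1]], return_counts=True
            )
            nz = comp_ids > 0
            comp = 0
            if nz.any():
                best = np.argmax(counts[nz])
                if counts[nz][best] / prop.area >= overlap_fraction:
                    comp = int(comp_ids[nz][best])
        if comp > 0:
            assignment[prop.label] = comp

    per_comp = pd.Series(assignment, dtype=int).value_counts()
    myotube_comps = per_comp[per_comp >= min_nuclei]
    n_in = int(myotube_comps.sum())
    n_total = len(props)
    return FusionResult(
        n_nuclei_total=n_total,
        n_nuclei_in_myotubes=n_in,
        fusion_index_pct=100.0 * n_in / n_total,
        myotubes=pd.DataFrame(
            {"component_id": myotube_comps.index.to_numpy(), "n_nuclei": myotube_comps.to_numpy()}
        ),
    )


@dataclass
class FibreAnnotation:
    """A manually traced fibre: ordered polyline plus assigned nucleus centroids."""

    fibre_id: int
    polyline: np.ndarray  # (N, 2) ordered (row, col) vertices, N >= 2
    centroids: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.polyline = np.asarray(self.polyline, dtype=float)
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        if self.polyline.ndim != 2 or self.polyline.shape[0] < 2 or self.polyline.shape[1] != 2:
            raise ValueError("polyline must be an (N>=2, 2) array of ordered coordinates")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass(frozen=True)
class SpacingResult:
    fibre_id: int
    fibre_length_um: float
    mean_spacing_um: float | None
    spacings_um: tuple[float, ...]


def internuclear_spacing(annotation: FibreAnnotation) -> SpacingResult:
    """Fibre arc length and internuclear spacing along the fibre.

    Centroids are projected onto the polyline; spacing is the arc-length
    distance between consecutive projections (fibres curve, so arc
    length, not straight-line distance).  With fewer than two centroids
    the spacing is absent but the length is still returned.
    """
    line = LineString(annotation.polyline)
    px = annotation.pixel_size_um
    length_um = float(line.length) * px
    if len(annotation.centroids) < 2:
        return SpacingResult(annotation.fibre_id, length_um, None, ())
    positions = np.sort([line.project(Point(*c)) for c in annotation.centroids])
    spacings = tuple(float(s) * px for s in np.diff(positions))
    return SpacingResult(
        annotation.fibre_id, length_um, float(np.mean(spacings)), spacings
    )


def read_fibre_annotations(
    polyline_csv, centroid_csv=None, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
) -> list[FibreAnnotation]:
    """Load fibre annotations from CSV.

    ``polyline_csv`` needs columns ``fibre_id, vertex_index, row, col``;
    ``centroid_csv`` (optional) needs ``fibre_id, row, col``.
    """
    poly = pd.read_csv(polyline_csv)
    cents = pd.read_csv(centroid_csv) if centroid_csv is not None else None
    out = []
    for fid, grp in poly.groupby("fibre_id"):
        grp = grp.sort_values("vertex_index")
        cen = (
            cents.loc[cents.fibre_id == fid, ["row", "col"]].to_numpy()
            if cents is not None
            else np.empty((0, 2))
        )
        out.append(
            FibreAnnotation(
                fibre_id=int(fid),
                polyline=grp[["row", "col"]].to_numpy(),
                centroids=cen,
                pixel_size_um=pixel_size_um,
            )
        )
    return out
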