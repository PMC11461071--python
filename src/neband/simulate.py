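"""Synthetic immunofluorescence fields with known ground truth.

Emulates single-plane widefield images of differentiating myoblast
cultures: round nuclei carrying a DNA stain (DAPI-like) and a nuclear
differentiation marker (MyoG-like), elongated syncytial regions carrying
a cytoplasmic marker (MHC-like), and one or two protein channels whose
intensity is a mixture of nuclear-envelope (NE) ring, nucleoplasm,
perinuclear-Golgi and dispersed-cytoplasm components.  Image formation
is Gaussian blur followed by Poisson shot noise and additive Gaussian
read noise, clipped at zero as camera data are.

Every nucleus is recorded in a :class:`GroundTruth` table (position,
radius, marker label, myotube membership, true NE enrichment) so that
segmentation, band morphometry, gating, fusion and the downstream
statistics can all be tested against known answers.

The true NE ring is the annulus straddling the nucleus boundary with a
configurable width (default 4 px), deliberately independent of any
measurement band geometry: ground truth must not be defined circularly
by the measurement.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi

from .io import FieldImage

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "PlacementError",
    "sample_layout",
    "render_field",
    "expected_field",
    "label_map",
    "mhc_mask",
    "ground_truth_fusion_index",
    "generate_coloc_pair",
]


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed without overlap."""


@dataclass(frozen=True)
class SimulationParams:
    """All knobs of the synthetic-field generator.

    Intensity levels are linear camera units (expected photon counts per
    pixel when ``photon_scale`` is 1).  ``ne_enrichment`` is the ratio of
    the NE-ring mean to the cytoplasm mean in the noiseless image, i.e.
    the quantity the band morphometry is meant to recover.
    """

    field_shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.102
    n_nuclei: int = 12
    nucleus_radius_px: tuple[float, float] = (9.0, 14.0)
    marker_positive_fraction: float = 0.6
    myotube_fraction: float = 0.0
    ne_enrichment: float = 4.0
    ne_enrichment2: float | None = None
    golgi_mode: str = "none"  # {"belt", "dispersed", "none"}
    nucleoplasm_level: float = 60.0
    cytoplasm_level: float = 100.0
    background_level: float = 0.0
    background_gradient: float = 0.0
    psf_sigma_px: float = 0.8
    read_noise_sd: float = 1.0
    photon_scale: float = 1.0
    seed: int = 0
    # geometry of the rendered structures
    ne_ring_width_px: float = 4.0
    golgi_band_px: float = 4.0
    dapi_level: float = 200.0
    marker_level: float = 200.0
    marker_negative_level: float = 20.0
    mhc_level: float = 150.0
    golgi_level: float = 300.0
    min_gap_px: float = 6.0
    border_margin_px: float = 12.0
    myotube_chain_size: tuple[int, int] = (2, 4)
    max_placement_tries: int = 2000

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        for name in ("marker_positive_fraction", "myotube_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "ne_enrichment",
            "nucleoplasm_level",
            "cytoplasm_level",
            "background_level",
            "psf_sigma_px",
            "read_noise_sd",
            "dapi_level",
            "marker_level",
            "marker_negative_level",
            "mhc_level",
            "golgi_level",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.photon_scale > 0:
            raise ValueError("photon_scale must be positive (use math.inf for no shot noise)")
        if self.golgi_mode not in ("belt", "dispersed", "none"):
            raise ValueError(f"unknown golgi_mode {self.golgi_mode!r}")
        lo, hi = self.nucleus_radius_px
        if not (0 < lo <= hi):
            raise ValueError("nucleus_radius_px must be an increasing positive (min, max) pair")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    def replace(self, **kwargs) -> "SimulationParams":
        return dataclasses.replace(self, **kwargs)

    def noise_free(self) -> "SimulationParams":
        """Same field, but no blur, no shot noise and no read noise."""
        return self.replace(psf_sigma_px=0.0, read_noise_sd=0.0, photon_scale=math.inf)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["photon_scale"] = "inf" if math.isinf(self.photon_scale) else self.photon_scale
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationParams":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("photon_scale") == "inf":
            d["photon_scale"] = math.inf
        for key in ("field_shape", "nucleus_radius_px", "myotube_chain_size"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-nucleus simulation truth plus the myotube (capsule) geometry.

    ``nuclei`` has one row per rendered nucleus with columns
    ``id, row, col, radius_px, marker_positive, myotube_id,
    ne_enrichment, golgi_mode`` (``myotube_id`` 0 = mononucleated).
    ``myotubes`` holds one capsule (thickened segment) per myotube.
    """

    nuclei: pd.DataFrame
    myotubes: pd.DataFrame
    params: SimulationParams
    seed: int

    def __post_init__(self) -> None:
        required = {
            "id",
            "row",
            "col",
            "radius_px",
            "marker_positive",
            "myotube_id",
            "ne_enrichment",
            "golgi_mode",
        }
        missing = required - set(self.nuclei.columns)
        if missing:
            raise ValueError(f"GroundTruth.nuclei missing columns {sorted(missing)}")

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclei)

    def to_csv(self, path) -> None:
        self.nuclei.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# layout


def _segment_point_distance(p0, p1, q) -> float:
    """Distance from point q to segment p0-p1 (all 2-vectors)."""
    p0, p1, q = np.asarray(p0, float), np.asarray(p1, float), np.asarray(q, float)
    d = p1 - p0
    denom = float(d @ d)
    if denom == 0:
        return float(np.hypot(*(q - p0)))
    t = np.clip((q - p0) @ d / denom, 0.0, 1.0)
    return float(np.hypot(*(q - (p0 + t * d))))


def _segment_segment_distance(a0, a1, b0, b1) -> float:
    # sampled-endpoint bound is not exact for crossing segments; check crossing first
    a0, a1, b0, b1 = (np.asarray(p, float) for p in (a0, a1, b0, b1))

    def _orient(p, q, r):
        return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])

    if (_orient(a0, a1, b0) * _orient(a0, a1, b1) < 0) and (
        _orient(b0, b1, a0) * _orient(b0, b1, a1) < 0
    ):
        return 0.0
    return min(
        _segment_point_distance(a0, a1, b0),
        _segment_point_distance(a0, a1, b1),
        _segment_point_distance(b0, b1, a0),
        _segment_point_distance(b0, b1, a1),
    )


def _chain_sizes(n_myo: int, size_range: tuple[int, int], rng) -> list[int]:
    lo, hi = size_range
    sizes: list[int] = []
    left = n_myo
    while left >= lo:
        s = int(rng.integers(lo, hi + 1))
        s = min(s, left)
        if left - s == 1:  # avoid a leftover singleton chain
            s = left
        sizes.append(s)
        left -= s
    if left > 0 and sizes:
        sizes[-1] += left
    return sizes


def sample_layout(params: SimulationParams) -> GroundTruth:
    """Place non-overlapping nuclei (and myotube capsules) on the field.

    Nuclei assigned to a myotube form a spatial chain along the capsule
    axis; mononucleated nuclei are placed outside every capsule.  Marker
    labels are Bernoulli draws with ``marker_positive_fraction``.
    Placement uses rejection sampling with a bounded retry budget.
    """
    rng = np.random.default_rng(params.seed)
    H, W = params.field_shape
    r_lo, r_hi = params.nucleus_radius_px
    margin = r_hi + params.border_margin_px
    if params.n_nuclei > 0 and (H - 2 * margin <= 0 or W - 2 * margin <= 0):
        raise PlacementError(
            f"field {params.field_shape} too small for nuclei of radius <= {r_hi} "
            f"with border margin {params.border_margin_px}"
        )

    n_myo = round(params.myotube_fraction * params.n_nuclei)
    if n_myo == 1:
        n_myo = 2 if params.n_nuclei >= 2 else 0
    chain_sizes = _chain_sizes(n_myo, params.myotube_chain_size, rng)

    capsule_r = r_hi + 5.0
    spacing = 2 * r_hi + 4.0
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    myotube_ids: list[int] = []
    capsules: list[dict] = []  # row0,col0,row1,col1,radius

    def _capsule_ok(p0, p1) -> bool:
        for cap in capsules:
            d = _segment_segment_distance(
                p0, p1, (cap["row0"], cap["col0"]), (cap["row1"], cap["col1"])
            )
            if d < capsule_r + cap["radius_px"] + params.min_gap_px:
                return False
        return True

    for chain_id, size in enumerate(chain_sizes, start=1):
        length = (size - 1) * spacing
        placed = False
        for _ in range(params.max_placement_tries):
            theta = rng.uniform(0, np.pi)
            mid = np.array(
                [rng.uniform(margin, H - margin), rng.uniform(margin, W - margin)]
            )
            axis = np.array([np.sin(theta), np.cos(theta)])
            p0 = mid - axis * length / 2
            p1 = mid + axis * length / 2
            pts = [p0 + axis * spacing * i for i in range(size)]
            if not all(
                margin <= p[0] <= H - margin and margin <= p[1] <= W - margin for p in pts
            ):
                continue
            if not _capsule_ok(p0, p1):
                continue
            capsules.append(
                {
                    "myotube_id": chain_id,
                    "row0": p0[0],
                    "col0": p0[1],
                    "row1": p1[0],
                    "col1": p1[1],
                    "radius_px": capsule_r,
                }
            )
            for p in pts:
                centers.append((p[0], p[1]))
                radii.append(float(rng.uniform(r_lo, r_hi)))
                myotube_ids.append(chain_id)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place myotube chain of {size} nuclei after "
                f"{params.max_placement_tries} tries; nucleus density too high for "
                f"field {params.field_shape}"
            )

    n_single = params.n_nuclei - n_myo
    for _ in range(n_single):
        placed = False
        for _ in range(params.max_placement_tries):
            p = (rng.uniform(margin, H - margin), rng.uniform(margin, W - margin))
            r = float(rng.uniform(r_lo, r_hi))
            ok = all(
                np.hypot(p[0] - c[0], p[1] - c[1]) >= r + rc + params.min_gap_px
                for c, rc in zip(centers, radii)
            )
            if ok:
                for cap in capsules:
                    d = _segment_point_distance(
                        (cap["row0"], cap["col0"]), (cap["row1"], cap["col1"]), p
                    )
                    if d < cap["radius_px"] + r + params.min_gap_px:
                        ok = False
                        break
            if ok:
                centers.append(p)
                radii.append(r)
                myotube_ids.append(0)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place nucleus {len(centers) + 1}/{params.n_nuclei} after "
                f"{params.max_placement_tries} tries; nucleus density too high for "
                f"field {params.field_shape}"
            )

    n = len(centers)
    marker = rng.random(n) < params.marker_positive_fraction
    nuclei = pd.DataFrame(
        {
            "id": np.arange(1, n + 1, dtype=int),
            "row": [c[0] for c in centers],
            "col": [c[1] for c in centers],
            "radius_px": radii,
            "marker_positive": marker,
            "myotube_id": myotube_ids,
            "ne_enrichment": params.ne_enrichment,
            "golgi_mode": params.golgi_mode,
        }
    )
    myotubes = pd.DataFrame(
        capsules, columns=["myotube_id", "row0", "col0", "row1", "col1", "radius_px"]
    )
    return GroundTruth(nuclei=nuclei, myotubes=myotubes, params=params, seed=params.seed)


# ---------------------------------------------------------------------------
# rendering


def label_map(truth: GroundTruth) -> np.ndarray:
    """Render the true nucleus label map (disc per nucleus, id = row id)."""
    H, W = truth.params.field_shape
    rr, cc = np.indices((H, W))
    labels = np.zeros((H, W), dtype=np.int32)
    for rec in truth.nuclei.itertuples():
        mask = (rr - rec.row) ** 2 + (cc - rec.col) ** 2 <= rec.radius_px**2
        labels[mask] = rec.id
    return labels


def mhc_mask(truth: GroundTruth) -> np.ndarray:
    """Boolean mask of the MHC-like syncytial (capsule) regions."""
    H, W = truth.params.field_shape
    rr, cc = np.indices((H, W))
    mask = np.zeros((H, W), dtype=bool)
    for cap in truth.myotubes.itertuples():
        p0 = np.array([cap.row0, cap.col0])
        d = np.array([cap.row1 - cap.row0, cap.col1 - cap.col0])
        denom = float(d @ d)
        if denom == 0:
            dist = np.hypot(rr - cap.row0, cc - cap.col0)
        else:
            t = np.clip(((rr - p0[0]) * d[0] + (cc - p0[1]) * d[1]) / denom, 0.0, 1.0)
            dist = np.hypot(rr - (p0[0] + t * d[0]), cc - (p0[1] + t * d[1]))
        mask |= dist <= cap.radius_px
    return mask


def _protein_expectation(truth: GroundTruth, params: SimulationParams, enrichment_col):
    H, W = params.field_shape
    rr, cc = np.indices((H, W))
    img = np.full((H, W), params.cytoplasm_level, dtype=float)
    half = params.ne_ring_width_px / 2.0

    golgi_rng = np.random.default_rng([params.seed, 2])
    if params.golgi_mode != "none":
        for rec in truth.nuclei.itertuples():
            d = np.hypot(rr - rec.row, cc - rec.col)
            if params.golgi_mode == "belt":
                belt = (d > rec.radius_px + half) & (
                    d <= rec.radius_px + half + params.golgi_band_px
                )
                img[belt] = params.golgi_level
            else:  # dispersed: small puncta scattered in the perinuclear cytoplasm
                for _ in range(6):
                    ang = golgi_rng.uniform(0, 2 * np.pi)
                    rad = golgi_rng.uniform(rec.radius_px + half + 1, rec.radius_px + 10)
                    pr, pc = rec.row + rad * np.sin(ang), rec.col + rad * np.cos(ang)
                    img[np.hypot(rr - pr, cc - pc) <= 2.0] = params.golgi_level

    for rec in truth.nuclei.itertuples():
        d = np.hypot(rr - rec.row, cc - rec.col)
        e = getattr(rec, enrichment_col)
        img[d <= rec.radius_px - half] = params.nucleoplasm_level
        ring = (d > rec.radius_px - half) & (d <= rec.radius_px + half)
        img[ring] = e * params.cytoplasm_level

    img += params.background_level
    if params.background_gradient:
        img += params.background_gradient * rr / max(H - 1, 1)
    return img


def expected_field(truth: GroundTruth, params: SimulationParams | None = None) -> FieldImage:
    """Noise-free expectation of every channel (blur applied, no noise)."""
    params = params or truth.params
    H, W = params.field_shape
    rr, cc = np.indices((H, W))

    nucleus = np.zeros((H, W), dtype=bool)
    marker = np.zeros((H, W), dtype=float)
    for rec in truth.nuclei.itertuples():
        mask = (rr - rec.row) ** 2 + (cc - rec.col) ** 2 <= rec.radius_px**2
        nucleus |= mask
        marker[mask] = (
            params.marker_level if rec.marker_positive else params.marker_negative_level
        )

    channels = {
        "dapi": np.where(nucleus, params.dapi_level, 0.0),
        "marker_nuclear": marker,
        "marker_cyto": np.where(mhc_mask(truth), params.mhc_level, 0.0),
        "protein": _protein_expectation(truth, params, "ne_enrichment"),
    }
    if params.ne_enrichment2 is not None:
        t2 = truth.nuclei.assign(ne_enrichment2=params.ne_enrichment2)
        channels["protein2"] = _protein_expectation(
            GroundTruth(t2, truth.myotubes, params, truth.seed), params, "ne_enrichment2"
        )

    if params.psf_sigma_px > 0:
        channels = {
            k: ndi.gaussian_filter(v, params.psf_sigma_px) for k, v in channels.items()
        }
    return FieldImage(channels=channels, pixel_size_um=params.pixel_size_um)


def render_field(
    truth: GroundTruth, params: SimulationParams | None = None, apply_noise: bool = True
) -> FieldImage:
    """Render the noisy field: blur, Poisson shot noise, Gaussian read noise.

    With ``photon_scale`` s, each pixel of expectation λ is drawn as
    Poisson(s·λ)/s, so the expectation is preserved and the shot-noise
    variance is λ/s; ``photon_scale = math.inf`` disables shot noise.
    Read noise is additive N(0, ``read_noise_sd``); the result is clipped
    at zero.  Identical (truth, params) reproduce a bit-identical field.
    """
    params = params or truth.params
    clean = expected_field(truth, params)
    if not apply_noise:
        return clean
    rng = np.random.default_rng([params.seed, 3])
    noisy = {}
    for name in clean.channel_names:  # fixed channel order keeps draws reproducible
        img = clean[name]
        if math.isfinite(params.photon_scale):
            img = rng.poisson(img * params.photon_scale) / params.photon_scale
        if params.read_noise_sd > 0:
            img = img + rng.normal(0.0, params.read_noise_sd, size=img.shape)
        noisy[name] = np.clip(img, 0.0, None)
    return FieldImage(channels=noisy, pixel_size_um=params.pixel_size_um)


def ground_truth_fusion_index(truth: GroundTruth) -> float:
    """Fusion index implied by the layout: % of nuclei in myotubes with >= 2 nuclei."""
    if truth.n_nuclei == 0:
        raise ValueError("no nuclei in ground truth")
    counts = truth.nuclei[truth.nuclei.myotube_id > 0].groupby("myotube_id").size()
    n_in = int(counts[counts >= 2].sum())
    return 100.0 * n_in / truth.n_nuclei


def generate_coloc_pair(
    rho: float,
    shape: tuple[int, int],
    seed: int,
    mean: float = 5.0,
    sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two non-negative channels with target Pearson correlation ``rho``.

    Built from a bivariate Gaussian field (x2 = rho·z1 + sqrt(1−rho²)·z2),
    shifted to ``mean`` and clipped at zero; with the default 5-sigma
    offset the clipping is negligible and the sample correlation
    converges to ``rho`` as the pixel count grows.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [-1, 1], got {rho}")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(shape)
    z2 = rng.standard_normal(shape)
    ch1 = np.clip(mean + sd * z1, 0.0, None)
    ch2 = np.clip(mean + sd * (rho * z1 + math.sqrt(1.0 - rho**2) * z2), 0.0, None)
    return ch1, ch2
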