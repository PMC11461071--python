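"""Pixel-wise colocalization coefficients (Pearson, Manders M1/M2).

Coefficients are computed within a region-of-interest mask (typically
the transduced cell), not the whole field.  Manders coefficients use a
per-channel threshold on the *other* channel: M1 is the fraction of
channel-1 intensity found where channel 2 is above its threshold, and
symmetrically for M2.  The default threshold rule is "zero" (any
positive co-channel intensity counts), which is the permissive
convention consistent with coefficients near 1 for genuinely
co-distributed stains; Otsu and absolute thresholds are available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

__all__ = ["pearson", "manders", "coloc_coefficients", "ColocResult"]


@dataclass(frozen=True)
class ColocResult:
    pearson_r: float
    manders_m1: float
    manders_m2: float
    threshold_ch1: float
    threshold_ch2: float
    n_pixels: int
    mask_name: str = "field"


def _masked(ch1, ch2, mask):
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    if ch1.shape != ch2.shape:
        raise ValueError("channels must share one shape")
    if mask is None:
        mask = np.ones(ch1.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != ch1.shape:
            raise ValueError("mask must be co-registered with the channels")
    return ch1[mask], ch2[mask]


def pearson(ch1: np.ndarray, ch2: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Sample Pearson correlation of two channels over a mask.

    Returns NaN with a warning if either channel is constant on the mask
    (the coefficient is undefined there).
    """
    x, y = _masked(ch1, ch2, mask)
    if x.size < 2:
        raise ValueError("pearson needs at least 2 mask pixels")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant channel on mask: Pearson r undefined, reported absent",
                      stacklevel=2)
        return float("nan")
    xd = x - x.mean()
    yd = y - y.mean()
    return float((xd @ yd) / np.sqrt((xd @ xd) * (yd @ yd)))


def _resolve_rule(values: np.ndarray, rule) -> float:
    if rule == "zero":
        return 0.0
    if rule == "otsu":
        if np.ptp(values) == 0:
            return float(values.flat[0])
        return float(threshold_otsu(values))
    if isinstance(rule, str) and rule.startswith("abs:"):
        return float(rule.split(":", 1)[1])
    if isinstance(rule, (int, float)) and not isinstance(rule, bool):
        return float(rule)
    if isinstance(rule, tuple) and len(rule) == 2 and rule[0] == "absolute":
        return float(rule[1])
    raise ValueError(f"unknown threshold rule {rule!r}")


def manders(
    ch1: np.ndarray,
    ch2: np.ndarray,
    mask: np.ndarray | None = None,
    threshold_rule="zero",
) -> tuple[float, float]:
    """Manders coefficients (M1, M2) over a mask.

    M1 = sum of ch1 where ch2 > t2, divided by the sum of ch1 over the
    mask; M2 symmetrically.  ``threshold_rule`` is ``"zero"`` (default),
    ``"otsu"``, ``"abs:<v>"``, a number, or ``("absolute", v)``; the same
    rule sets t1 and t2 on their own channels.  A channel with zero total
    intensity makes its coefficient undefined (NaN, with a warning).
    """
    x, y = _masked(ch1, ch2, mask)
    if x.size == 0:
        raise ValueError("manders needs a non-empty mask")
    t1 = _resolve_rule(x, threshold_rule)
    t2 = _resolve_rule(y, threshold_rule)
    sx, sy = x.sum(), y.sum()
    if sx == 0:
        warnings.warn("channel 1 sums to zero on mask: M1 undefined", stacklevel=2)
        m1 = float("nan")
    else:
        m1 = float(x[y > t2].sum() / sx)
    if sy == 0:
        warnings.warn("channel 2 sums to zero on mask: M2 undefined", stacklevel=2)
        m2 = float("nan")
    else:
        m2 = float(y[x > t1].sum() / sy)
    return m1, m2


def coloc_coefficients(
    ch1: np.ndarray,
    ch2: np.ndarray,
    mask: np.ndarray | None = None,
    threshold_rule="zero",
    mask_name: str = "field",
) -> ColocResult:
    """Pearson r plus Manders M1/M2 in one result record."""
    x, y = _masked(ch1, ch2, mask)
    r = pearson(ch1, ch2, mask)
    m1, m2 = manders(ch1, ch2, mask, threshold_rule)
    return ColocResult(
        pearson_r=r,
        manders_m1=m1,
        manders_m2=m2,
        threshold_ch1=_resolve_rule(x, threshold_rule),
        threshold_ch2=_resolve_rule(y, threshold_rule),
        n_pixels=int(x.size),
        mask_name=mask_name,
    )
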