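import numpy as np
import pytest

from neband.simulate import SimulationParams, render_field, sample_layout


def make_disc_labels(shape, discs):
    """Label map with discs given as (row, col, radius) triples, ids 1..n."""
    rr, cc = np.indices(shape)
    labels = np.zeros(shape, dtype=np.int32)
    for i, (r, c, rad) in enumerate(discs, start=1):
        labels[(rr - r) ** 2 + (cc - c) ** 2 <= rad**2] = i
    return labels


def random_disc_labels(rng, max_side=128, max_discs=3):
    """Random non-overlapping disc label map for geometry oracle tests."""
    H = int(rng.integers(64, max_side + 1))
    W = int(rng.integers(64, max_side + 1))
    n = int(rng.integers(1, max_discs + 1))
    discs = []
    for _ in range(200):
        if len(discs) == n:
            break
        rad = float(rng.uniform(4, 12))
        r = float(rng.uniform(rad + 1, H - rad - 1))
        c = float(rng.uniform(rad + 1, W - rad - 1))
        if all(np.hypot(r - r0, c - c0) > rad + rad0 + 2 for r0, c0, rad0 in discs):
            discs.append((r, c, rad))
    return make_disc_labels((H, W), discs)


def bruteforce_nearest(labels):
    """Per-pixel nearest object and distance by direct pairwise distances.

    Independent oracle for the Euclidean nearest-object rule: for every
    pixel, the distance to each object is the minimum distance to any of
    that object's pixel centres; ties go to the smaller label id.
    """
    from scipy.spatial.distance import cdist

    H, W = labels.shape
    coords = np.argwhere(np.ones_like(labels)).astype(float)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    best = np.full(H * W, np.inf)
    near = np.zeros(H * W, dtype=int)
    for i in ids:  # ascending ids: strict '<' keeps ties with the smaller id
        pts = np.argwhere(labels == i).astype(float)
        d = cdist(coords, pts).min(axis=1)
        upd = d < best
        near[upd] = i
        best[upd] = d[upd]
    return near.reshape(H, W), best.reshape(H, W)


def bruteforce_outer_bands(labels, width, n_bands, shift):
    """Band stack from the per-pixel distance-interval rule (oracle)."""
    near, dist = bruteforce_nearest(labels)
    stack = np.zeros((n_bands,) + labels.shape, dtype=np.int32)
    bg = labels == 0
    for k in range(1, n_bands + 1):
        lo, hi = shift + (k - 1) * width, shift + k * width
        sel = bg & (dist > lo) & (dist <= hi)
        stack[k - 1][sel] = near[sel]
    return stack


def bruteforce_inner_bands(labels, width, n_bands):
    """Inner bands from per-pixel distance to the object's complement (oracle)."""
    from scipy.spatial.distance import cdist

    stack = np.zeros((n_bands,) + labels.shape, dtype=np.int32)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    for i in ids:
        inside = np.argwhere(labels == i).astype(float)
        outside = np.argwhere(labels != i).astype(float)
        d = cdist(inside, outside).min(axis=1)
        for k in range(1, n_bands + 1):
            lo, hi = (k - 1) * width, k * width
            sel = inside[(d > lo) & (d <= hi)].astype(int)
            stack[k - 1][sel[:, 0], sel[:, 1]] = i
    return stack


@pytest.fixture(scope="session")
def clean_params():
    """Small noise-free field: 6 nuclei, E=4, no blur, no noise."""
    return SimulationParams(
        field_shape=(192, 192), n_nuclei=6, ne_enrichment=4.0, seed=11
    ).noise_free()


@pytest.fixture(scope="session")
def clean_field(clean_params):
    truth = sample_layout(clean_params)
    field = render_field(truth, clean_params)
    return truth, field
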