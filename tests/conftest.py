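"""Shared fixtures: small synthetic scenes and independent geometry oracles."""

from itertools import combinations

import numpy as np
import pytest

from macquant.synthdata import SyntheticConfig, generate_domain_sequence


# ---------------------------------------------------------------------------
# oracles (independent of the implementations they check)


def brute_force_delaunay_edges(points: np.ndarray) -> set:
    """Delaunay edge set by exhaustive empty-circumcircle testing, O(n^4).

    A triangle belongs to the Delaunay triangulation iff no other point lies
    strictly inside its circumcircle; the union of such triangles' edges is
    the Delaunay edge set.  For cocircular ties (points exactly on the
    circle) the triangle is accepted, so tied configurations yield the union
    of the tied triangulations' edges.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    edges = set()
    for i, j, k in combinations(range(n), 3):
        a, b, c = pts[i], pts[j], pts[k]
        area2 = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        if abs(area2) < 1e-12:
            continue
        center, r2 = _circumcircle(a, b, c)
        ok = True
        for m in range(n):
            if m in (i, j, k):
                continue
            d2 = np.sum((pts[m] - center) ** 2)
            if d2 < r2 - 1e-9 * max(r2, 1.0):
                ok = False
                break
        if ok:
            edges |= {tuple(sorted(p)) for p in ((i, j), (j, k), (i, k))}
    return edges


def _circumcircle(a, b, c):
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
          + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
          + (cx**2 + cy**2) * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, float(np.sum((a - center) ** 2))


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    return float(np.logical_and(a, b).sum() / union) if union else 1.0


# ---------------------------------------------------------------------------
# scenes


@pytest.fixture(scope="session")
def disk_scene():
    """One static noiseless circular domain, radius 10 um on a 40 um field."""
    config = SyntheticConfig(
        image_shape=(200, 200), pixel_size=0.2, n_frames=1, n_domains=1,
        domain_radius_range=(10.0, 10.0), domain_irregularity=0.0,
        background_amplitude=0.0, noise_sigma=0.0, seed=0)
    seq, truth = generate_domain_sequence(config)
    return config, seq, truth


@pytest.fixture(scope="session")
def noisy_scene():
    """Default acquisition conditions: 4 irregular domains, noise + gradient."""
    config = SyntheticConfig(n_frames=3, n_domains=4, seed=1)
    seq, truth = generate_domain_sequence(config)
    return config, seq, truth


@pytest.fixture(scope="session")
def split_scene():
    """Contraction-style script: one domain splits in two at frame 5."""
    config = SyntheticConfig(
        n_frames=10, n_domains=2, seed=4,
        event_script=({"frame": 5, "kind": "split", "domain_ids": (0,),
                       "params": {}},))
    seq, truth = generate_domain_sequence(config)
    return config, seq, truth


@pytest.fixture(scope="session")
def fuse_scene():
    """Two dark Lo domains fuse into one at frame 4 (count drops by one)."""
    config = SyntheticConfig(
        n_frames=8, n_domains=2, seed=5, domain_phase="dark_Lo_on_bright_Ld",
        event_script=({"frame": 4, "kind": "fuse", "domain_ids": (0, 1),
                       "params": {}},))
    seq, truth = generate_domain_sequence(config)
    return config, seq, truth


@pytest.fixture(scope="session")
def kinetic_scene():
    """Sequence whose true total contour follows L_final=100 um, tau=5 min,
    t0=1 min; baseline perimeter large so the added deformation is gentle."""
    config = SyntheticConfig(
        image_shape=(480, 480), n_frames=8, n_domains=16, seed=2,
        frame_interval=200.0, domain_radius_range=(3.0, 4.2),
        kinetic_params=(100.0, 5.0, 1.0))
    seq, truth = generate_domain_sequence(config)
    return config, seq, truth


@pytest.fixture(scope="session")
def kinetic_segmentation(kinetic_scene):
    from macquant.segment import SegmentationParams, segment_sequence

    config, seq, _ = kinetic_scene
    return segment_sequence(seq.channel(0), SegmentationParams(),
                            pixel_size_um=config.pixel_size)
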