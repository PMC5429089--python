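"""Synthetic two-channel fluorescence time-lapse generator with ground truth.

Emulates TIRF acquisitions of a phase-separated supported bilayer under a
reconstituted actin cortex: micrometer-scale liquid-ordered (Lo) /
liquid-disordered (Ld) domains on an uneven illumination background with
additive noise, domains that translate, deform, split and fuse over time
while the total Lo-phase area stays constant, diffraction-limited bright
actomyosin cluster spots in the actin channel, and optionally a scripted
mono-exponential growth of the total boundary contour length.

Domains are Fourier-perturbed circles rendered as anti-aliased filled
polygons, so every frame has an analytic (polygon-exact) area and perimeter
against which the measurement pipeline can be validated.  All randomness
(initial placement, mode phases, noise, cluster positions) is drawn from a
single seeded generator per sequence; shape events themselves are scripted
and deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from shapely.geometry import Polygon
from shapely.ops import unary_union
from scipy.optimize import brentq
from skimage.draw import polygon2mask

from .models import monoexponential
from .sequence import ImageSequence, save_tiff

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "Event",
    "GenerationError",
    "generate_domain_sequence",
    "generate_kinetic_series",
    "generate_cluster_frame",
    "save_sequence",
]

_POLY_PTS = 512  # vertices per blob polygon; perimeters converge well below 0.1%
_SUPERSAMPLE = 4  # anti-aliasing factor for rasterization
_DEFAULT_KINETIC_MODE = 3  # perimeter-tuning harmonic: low enough that the
# added boundary structure stays well above the optical/morphological scale
# and the measurement pipeline can resolve it


class GenerationError(RuntimeError):
    """Raised when a scene cannot be generated (packing, bounds, targets)."""


@dataclass(frozen=True)
class Event:
    """One scripted morphological event.

    kind
        ``split``: replace one domain by two equal-area children at this
        frame.  ``fuse``: replace two domains by one of summed area.
        ``translate``: move domains by a per-frame step from this frame on.
        ``deform``: grow a shape-mode amplitude from this frame on.
    params
        split: ``axis_deg`` (separation axis), ``gap_px``.
        fuse: none.
        translate: ``step_um`` = (dx, dy) per frame.
        deform: ``mode`` (harmonic), ``rate`` (amplitude per frame,
        relative), ``max_amplitude``.
    """

    frame: int
    kind: str
    domain_ids: tuple
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("split", "fuse", "translate", "deform"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        object.__setattr__(self, "domain_ids", tuple(int(i) for i in self.domain_ids))


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic acquisition.

    Defaults mirror the experimental conditions being emulated: 100x EMCCD
    TIRF imaging (0.16 um/px), interleaved two-color frames every 2.5 s,
    micrometer-scale domains, and a bright-Ld membrane channel (the membrane
    dye partitions to the Ld phase).
    """

    image_shape: tuple = (256, 256)  # (rows, cols) px
    pixel_size: float = 0.16  # um/px
    frame_interval: float = 2.5  # s
    n_frames: int = 1
    n_domains: int = 5
    domain_radius_range: tuple = (2.0, 4.0)  # um
    domain_phase: str = "bright_Ld_on_dark_Lo"
    domain_irregularity: float = 0.05  # max relative amplitude of shape modes; 0 = circles
    background_amplitude: float = 0.2  # relative illumination gradient, [0, 1)
    noise_sigma: float = 0.02  # fraction of dynamic range
    n_clusters: int = 0
    cluster_sigma: float = 3.0  # px
    event_script: tuple = ()
    kinetic_params: tuple | None = None  # (L_final um, tau min, t0 min)
    kinetic_mode: int = _DEFAULT_KINETIC_MODE
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.domain_phase not in ("bright_Ld_on_dark_Lo", "dark_Lo_on_bright_Ld"):
            raise ValueError(f"unknown domain_phase {self.domain_phase!r}")
        if not 0 <= self.background_amplitude < 1:
            raise ValueError("background_amplitude must be in [0, 1)")
        rmax_px = max(self.domain_radius_range) / self.pixel_size
        if 2 * rmax_px * 1.2 > min(self.image_shape):
            raise ValueError("domain radii do not fit inside the image")
        self.event_script = tuple(
            e if isinstance(e, Event) else Event(**e) for e in self.event_script
        )

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("image_shape", "domain_radius_range", "kinetic_params"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dict(self.__dict__)
        d["image_shape"] = list(self.image_shape)
        d["domain_radius_range"] = list(self.domain_radius_range)
        d["kinetic_params"] = list(self.kinetic_params) if self.kinetic_params else None
        d["event_script"] = [
            {"frame": e.frame, "kind": e.kind, "domain_ids": list(e.domain_ids),
             "params": e.params} for e in self.event_script
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class GroundTruth:
    """Per-frame truth for a generated sequence.

    ``masks`` follows the segmentation convention: True = bright (Ld) phase.
    ``domain_areas_um2`` lists the area of each scripted domain (the
    dispersed phase), frame by frame; ``lo_area_um2`` is the total
    liquid-ordered area, which stays constant under translate / deform /
    split / fuse scripts.  ``kinetic_curve_um`` holds the scripted
    contour-length change at each frame time when kinetics were requested.
    """

    masks: np.ndarray  # (n_frames, rows, cols) bool, True = Ld phase
    times_min: np.ndarray
    contour_length_um: np.ndarray
    domain_areas_um2: list  # per frame: array of per-domain areas
    domain_count: np.ndarray
    lo_area_um2: np.ndarray
    cluster_centroids_um: np.ndarray  # (n_clusters, 2), (x, y) um
    kinetic_curve_um: np.ndarray | None = None


# ---------------------------------------------------------------------------
# blob geometry


@dataclass
class _Blob:
    id: int
    center: np.ndarray  # (row, col) px
    r0: float  # px
    modes: list  # [harmonic, amplitude, phase]
    target_area_px: float  # polygon area conserved across frames
    kin_phase: float = 0.0
    kin_mode: int = _DEFAULT_KINETIC_MODE

    def copy(self) -> "_Blob":
        return _Blob(self.id, self.center.copy(), self.r0,
                     [list(m) for m in self.modes], self.target_area_px,
                     self.kin_phase, self.kin_mode)


def _blob_vertices(blob: _Blob, kin_amp: float = 0.0, n: int = _POLY_PTS) -> np.ndarray:
    theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    r = np.ones(n)
    for k, amp, phase in blob.modes:
        r += amp * np.cos(k * theta + phase)
    if kin_amp:
        r += kin_amp * np.cos(blob.kin_mode * theta + blob.kin_phase)
    r = np.clip(r, 0.05, None) * blob.r0
    rows = blob.center[0] + r * np.sin(theta)
    cols = blob.center[1] + r * np.cos(theta)
    return np.column_stack([rows, cols])


def _blob_polygon(blob: _Blob, kin_amp: float = 0.0) -> Polygon:
    return Polygon(_blob_vertices(blob, kin_amp))


def _renormalize_area(blob: _Blob, kin_amp: float = 0.0) -> None:
    """Rescale r0 so the polygon area equals the blob's conserved target.

    The polygon radius is linear in r0, so one multiplicative correction
    restores the area exactly.
    """
    area = _blob_polygon(blob, kin_amp).area
    blob.r0 *= np.sqrt(blob.target_area_px / area)


def _scene_union(blobs, kin_amp: float = 0.0):
    return unary_union([_blob_polygon(b, kin_amp) for b in blobs]) if blobs else None


def _check_bounds(blobs, shape, kin_amp=0.0):
    for b in blobs:
        v = _blob_vertices(b, kin_amp)
        if (v[:, 0].min() < 0 or v[:, 1].min() < 0
                or v[:, 0].max() > shape[0] - 1 or v[:, 1].max() > shape[1] - 1):
            raise GenerationError(f"domain {b.id} leaves the field of view")


def _check_packing(blobs, threshold_frac=1e-6):
    polys = {b.id: _blob_polygon(b) for b in blobs}
    ids = sorted(polys)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            inter = polys[a].intersection(polys[b]).area
            if inter > threshold_frac * min(polys[a].area, polys[b].area):
                raise GenerationError(
                    f"initial domains overlap beyond packing threshold: ids {a} and {b}")


def _initial_blobs(config: SyntheticConfig, rng: np.random.Generator) -> list:
    rmin, rmax = (r / config.pixel_size for r in sorted(config.domain_radius_range))
    blobs = []
    margin_factor = 1.35
    for bid in range(config.n_domains):
        r0 = rng.uniform(rmin, rmax)
        modes = []
        for k in rng.choice(np.arange(2, 6), size=2, replace=False):
            modes.append([int(k), rng.uniform(0.0, config.domain_irregularity),
                          rng.uniform(0, 2 * np.pi)])
        placed = False
        for _ in range(300):
            margin = r0 * margin_factor
            center = np.array([
                rng.uniform(margin, config.image_shape[0] - 1 - margin),
                rng.uniform(margin, config.image_shape[1] - 1 - margin),
            ])
            cand = _Blob(bid, center, r0, [list(m) for m in modes], 0.0,
                         kin_phase=rng.uniform(0, 2 * np.pi),
                         kin_mode=config.kinetic_mode)
            cand.target_area_px = _blob_polygon(cand).area
            clear = all(
                np.linalg.norm(cand.center - b.center) > 1.15 * (cand.r0 + b.r0)
                for b in blobs)
            if clear:
                blobs.append(cand)
                placed = True
                break
        if not placed:
            raise GenerationError(
                f"could not place domain {bid} without overlap; "
                f"reduce n_domains or domain_radius_range")
    _check_packing(blobs)
    return blobs


# ---------------------------------------------------------------------------
# scripted evolution


def _apply_instant_events(blobs, events, frame, config, rng):
    """Apply split/fuse events scheduled at this frame; returns new list."""
    by_id = {b.id: b for b in blobs}
    next_id = max(by_id, default=-1) + 1
    for ev in events:
        if ev.frame != frame or ev.kind not in ("split", "fuse"):
            continue
        missing = [i for i in ev.domain_ids if i not in by_id]
        if missing:
            raise GenerationError(
                f"event at frame {frame} references unknown domain ids {missing}")
        if ev.kind == "split":
            (pid,) = ev.domain_ids
            parent = by_id.pop(pid)
            axis = np.deg2rad(ev.params.get("axis_deg", rng.uniform(0, 180)))
            child_r0 = parent.r0 / np.sqrt(2)
            gap = ev.params.get("gap_px", 0.3 * child_r0)
            offset = (child_r0 + gap / 2.0) * np.array([np.sin(axis), np.cos(axis)])
            for sign in (-1.0, 1.0):
                child = _Blob(next_id, parent.center + sign * offset, child_r0,
                              [list(m) for m in parent.modes],
                              parent.target_area_px / 2.0,
                              kin_phase=rng.uniform(0, 2 * np.pi),
                              kin_mode=parent.kin_mode)
                _renormalize_area(child)
                by_id[next_id] = child
                next_id += 1
        else:  # fuse
            if len(ev.domain_ids) != 2:
                raise GenerationError("fuse event needs exactly two domain ids")
            a = by_id.pop(ev.domain_ids[0])
            b = by_id.pop(ev.domain_ids[1])
            total = a.target_area_px + b.target_area_px
            center = (a.center * a.target_area_px + b.center * b.target_area_px) / total
            merged = _Blob(next_id, center, np.hypot(a.r0, b.r0),
                           [list(m) for m in a.modes], total,
                           kin_phase=rng.uniform(0, 2 * np.pi),
                           kin_mode=a.kin_mode)
            _renormalize_area(merged)
            by_id[next_id] = merged
            next_id += 1
    return [by_id[i] for i in sorted(by_id)]


def _apply_continuous_events(blobs, events, frame, config):
    """Apply the per-frame step of active translate/deform events in place."""
    by_id = {b.id: b for b in blobs}
    for ev in events:
        if ev.kind not in ("translate", "deform") or frame < ev.frame:
            continue
        for did in ev.domain_ids:
            b = by_id.get(did)
            if b is None:
                continue  # id consumed by a split/fuse; event expires with it
            if ev.kind == "translate":
                dx, dy = ev.params.get("step_um", (0.2, 0.0))
                # (x, y) um -> (row, col) px; y increases with row
                b.center = b.center + np.array([dy, dx]) / config.pixel_size
            else:
                mode = int(ev.params.get("mode", 3))
                rate = float(ev.params.get("rate", 0.01))
                amax = float(ev.params.get("max_amplitude", 0.25))
                for m in b.modes:
                    if m[0] == mode:
                        m[1] = min(m[1] + rate, amax)
                        break
                else:
                    b.modes.append([mode, min(rate, amax), 0.0])
                _renormalize_area(b)
    return blobs


def _solve_kinetic_amplitude(blobs, target_perimeter_px: float) -> float:
    """Shared harmonic amplitude giving the requested total union perimeter.

    Each blob is area-renormalized at every trial amplitude, so the target
    perimeter is reached at exactly conserved per-domain areas.
    """

    def perimeter_at(a: float) -> float:
        trial = [b.copy() for b in blobs]
        for b in trial:
            _renormalize_area(b, a)
        return _scene_union(trial, a).length

    lo, hi = 0.0, 0.55
    if perimeter_at(hi) < target_perimeter_px:
        raise GenerationError(
            "kinetic contour target unattainable: requested total perimeter "
            f"{target_perimeter_px:.1f} px exceeds the maximum reachable by "
            "shape deformation; lower L_final or add domains")
    if perimeter_at(lo) >= target_perimeter_px:
        return 0.0
    return brentq(lambda a: perimeter_at(a) - target_perimeter_px, lo, hi,
                  xtol=1e-5)


# ---------------------------------------------------------------------------
# rendering


def _illumination_surface(shape, amplitude: float) -> np.ndarray:
    """Multiplicative low-order polynomial illumination field, mean ~1."""
    if amplitude == 0:
        return np.ones(shape)
    yy, xx = np.meshgrid(np.linspace(-0.5, 0.5, shape[0]),
                         np.linspace(-0.5, 0.5, shape[1]), indexing="ij")
    s = 1.0 * xx + 0.7 * yy + 0.8 * xx * yy - 0.5 * (xx**2 - 1 / 12) + 0.4 * (yy**2 - 1 / 12)
    s = s / np.abs(s).max()
    return 1.0 + amplitude * s


def _coverage(blobs, shape, kin_amp: float = 0.0) -> np.ndarray:
    """Anti-aliased domain occupancy in [0, 1] via supersampled rasterization."""
    ss = _SUPERSAMPLE
    big = np.zeros((shape[0] * ss, shape[1] * ss), dtype=bool)
    for b in blobs:
        v = _blob_vertices(b, kin_amp) * ss + (ss - 1) / 2.0
        big |= polygon2mask(big.shape, v)
    return big.reshape(shape[0], ss, shape[1], ss).mean(axis=(1, 3))


_BG_LEVEL = 0.2  # dark-phase intensity, fraction of dynamic range
_FG_LEVEL = 1.0  # bright-phase intensity


def _render_membrane(coverage, config, illum, rng) -> np.ndarray:
    if config.domain_phase == "bright_Ld_on_dark_Lo":
        img = _BG_LEVEL + (_FG_LEVEL - _BG_LEVEL) * coverage
    else:
        img = _FG_LEVEL - (_FG_LEVEL - _BG_LEVEL) * coverage
    img = img * illum
    if config.noise_sigma > 0:
        img = img + rng.normal(0.0, config.noise_sigma, img.shape)
    return img


def _render_actin(coverage, config, illum, centroids_px, rng) -> np.ndarray:
    # actin (and its biotin anchor) partitions to the Lo phase
    lo_cov = coverage if config.domain_phase == "dark_Lo_on_bright_Ld" else 1.0 - coverage
    img = 0.15 + 0.45 * lo_cov
    if len(centroids_px):
        yy, xx = np.mgrid[0:config.image_shape[0], 0:config.image_shape[1]]
        s2 = 2.0 * config.cluster_sigma**2
        for r, c in centroids_px:
            img = img + np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / s2)
    img = img * illum
    if config.noise_sigma > 0:
        img = img + rng.normal(0.0, config.noise_sigma, img.shape)
    return img


def _place_clusters(config, rng) -> np.ndarray:
    """Uniform cluster centroids (row, col) px with a margin for the spot."""
    if config.n_clusters == 0:
        return np.zeros((0, 2))
    m = 4.0 * config.cluster_sigma
    return np.column_stack([
        rng.uniform(m, config.image_shape[0] - 1 - m, config.n_clusters),
        rng.uniform(m, config.image_shape[1] - 1 - m, config.n_clusters),
    ])


# ---------------------------------------------------------------------------
# public operations


def generate_domain_sequence(config: SyntheticConfig):
    """Generate a two-channel time lapse plus exhaustive ground truth.

    The membrane channel renders the domain field under a multiplicative
    illumination gradient with additive Gaussian noise; the actin channel
    renders the complementary (Lo) phase texture plus Gaussian cluster
    spots.  Ground truth (masks, polygon-exact areas and perimeters, domain
    counts, Lo area, cluster positions) is filled for every frame.

    Returns
    -------
    (ImageSequence, GroundTruth)
    """
    rng = np.random.default_rng(config.seed)
    blobs = _initial_blobs(config, rng)
    centroids_px = _place_clusters(config, rng)
    illum = _illumination_surface(config.image_shape, config.background_amplitude)

    times = np.arange(config.n_frames) * config.frame_interval / 60.0  # min
    px = config.pixel_size
    frame_area_um2 = config.image_shape[0] * config.image_shape[1] * px * px

    kinetic_curve = None
    baseline_perim_px = None
    if config.kinetic_params is not None:
        Lf, tau, t0 = config.kinetic_params
        if tau <= 0:
            raise ValueError("kinetic tau must be positive")
        kinetic_curve = monoexponential(times, Lf, tau, t0)
        u0 = _scene_union(blobs)
        baseline_perim_px = u0.length if u0 is not None else 0.0
        if baseline_perim_px == 0.0 and np.any(kinetic_curve > 0):
            raise GenerationError("kinetic script needs at least one domain")

    frames = np.zeros((config.n_frames, 2, *config.image_shape))
    masks = np.zeros((config.n_frames, *config.image_shape), dtype=bool)
    contour_um = np.zeros(config.n_frames)
    lo_um2 = np.zeros(config.n_frames)
    counts = np.zeros(config.n_frames, dtype=int)
    per_domain = []

    for f in range(config.n_frames):
        blobs = _apply_instant_events(blobs, config.event_script, f, config, rng)
        blobs = _apply_continuous_events(blobs, config.event_script, f, config)
        kin_amp = 0.0
        if kinetic_curve is not None and kinetic_curve[f] > 0:
            target = baseline_perim_px + kinetic_curve[f] / px
            kin_amp = _solve_kinetic_amplitude(blobs, target)
            for b in blobs:
                _renormalize_area(b, kin_amp)
        _check_bounds(blobs, config.image_shape, kin_amp)

        union = _scene_union(blobs, kin_amp)
        if union is None or union.is_empty:
            geoms, perim, areas = [], 0.0, np.zeros(0)
        else:
            geoms = list(union.geoms) if union.geom_type == "MultiPolygon" else [union]
            perim = union.length
            areas = np.array([g.area for g in geoms])

        cov = _coverage(blobs, config.image_shape, kin_amp)
        domain_mask = cov >= 0.5
        masks[f] = domain_mask if config.domain_phase == "bright_Ld_on_dark_Lo" \
            else ~domain_mask
        contour_um[f] = perim * px
        counts[f] = len(geoms)
        per_domain.append(areas * px * px)
        domain_area_um2 = float(areas.sum()) * px * px
        lo_um2[f] = domain_area_um2 if config.domain_phase == "dark_Lo_on_bright_Ld" \
            else frame_area_um2 - domain_area_um2

        frames[f, 0] = _render_membrane(cov, config, illum, rng)
        frames[f, 1] = _render_actin(cov, config, illum, centroids_px, rng)

    centroids_um = np.column_stack([centroids_px[:, 1], centroids_px[:, 0]]) * px \
        if len(centroids_px) else np.zeros((0, 2))
    seq = ImageSequence(frames, pixel_size_um=px,
                        frame_interval_s=config.frame_interval)
    truth = GroundTruth(masks=masks, times_min=times, contour_length_um=contour_um,
                        domain_areas_um2=per_domain, domain_count=counts,
                        lo_area_um2=lo_um2, cluster_centroids_um=centroids_um,
                        kinetic_curve_um=kinetic_curve)
    return seq, truth


def generate_kinetic_series(params, times_min, noise_sigma_um: float = 0.0,
                            seed: int = 0) -> np.ndarray:
    """Sample the mono-exponential contour-growth model at given times.

    Parameters
    ----------
    params
        (L_final um, tau min, t0 min).
    times_min
        Sample times in minutes, all >= t0.
    noise_sigma_um
        Standard deviation of additive Gaussian noise (0 = exact curve).

    Returns
    -------
    Array of shape (n, 2) with columns (t, L); L(t0) is exactly 0 when
    noise is disabled.
    """
    Lf, tau, t0 = params
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.asarray(times_min, dtype=float)
    if np.any(t < t0):
        raise ValueError(f"all times must be >= t0 = {t0}")
    L = monoexponential(t, Lf, tau, t0)
    if noise_sigma_um > 0:
        L = L + np.random.default_rng(seed).normal(0.0, noise_sigma_um, t.shape)
    return np.column_stack([t, L])


def generate_cluster_frame(centroids_um, config: SyntheticConfig) -> np.ndarray:
    """Single actin-channel frame with Gaussian spots at given (x, y) um.

    Raises a GenerationError if any centroid falls outside the field of view.
    """
    rng = np.random.default_rng(config.seed)
    centroids_um = np.asarray(centroids_um, dtype=float).reshape(-1, 2)
    px = config.pixel_size
    centroids_px = np.column_stack([centroids_um[:, 1], centroids_um[:, 0]]) / px \
        if len(centroids_um) else np.zeros((0, 2))
    h, w = config.image_shape
    for i, (r, c) in enumerate(centroids_px):
        if not (0 <= r <= h - 1 and 0 <= c <= w - 1):
            raise GenerationError(f"cluster centroid {i} outside field of view")
    illum = _illumination_surface(config.image_shape, config.background_amplitude)
    return _render_actin(np.zeros(config.image_shape), config, illum,
                         centroids_px, rng)


def save_sequence(seq: ImageSequence, truth: GroundTruth, outdir,
                  interleaved: bool = True, write_masks: bool = True) -> dict:
    """Write TIFF stack(s), a JSON ground-truth sidecar and mask PNGs.

    Returns a manifest dict mapping product names to paths.
    """
    from imageio.v3 import imwrite as png_write

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = save_tiff(seq, outdir / "sequence.tif", interleaved=interleaved)
    manifest = {"tiff": [str(p) for p in paths]}
    sidecar = {
        "times_min": truth.times_min.tolist(),
        "contour_length_um": truth.contour_length_um.tolist(),
        "domain_areas_um2": [a.tolist() for a in truth.domain_areas_um2],
        "domain_count": truth.domain_count.tolist(),
        "lo_area_um2": truth.lo_area_um2.tolist(),
        "cluster_centroids_um": truth.cluster_centroids_um.tolist(),
        "kinetic_curve_um": (truth.kinetic_curve_um.tolist()
                             if truth.kinetic_curve_um is not None else None),
    }
    gt_path = outdir / "ground_truth.json"
    gt_path.write_text(json.dumps(sidecar, indent=1))
    manifest["ground_truth"] = str(gt_path)
    if write_masks:
        mask_paths = []
        for f in range(truth.masks.shape[0]):
            p = outdir / f"mask_{f:04d}.png"
            png_write(p, (truth.masks[f] * 255).astype(np.uint8))
            mask_paths.append(str(p))
        manifest["masks"] = mask_paths
    return manifest
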