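"""Lipid-domain segmentation of the membrane (DiD) channel.

The chain mirrors the published recipe: correct the uneven illumination
background, classify the dye signal with a local adaptive threshold, detect
the phase boundaries with Canny edge detection, combine both binary images
with XOR, refine with a morphological closing, remove small holes, and
finally merge in small objects found by the Laplacian-of-Gaussian detector.
Connected components of the resulting mask are labeled and measured.

The operator parameters (block sizes, sigmas, radii) are calibrated against
the synthetic fixtures and exposed in :class:`SegmentationParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import feature, filters, measure, morphology

__all__ = [
    "SegmentationParams",
    "LabeledDomains",
    "correct_background",
    "segment_frame",
    "assign_phase",
    "segment_sequence",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the segmentation chain.

    adaptive_block_size
        Odd window (px) of the local adaptive threshold; should be about
        4x the expected domain diameter so domains do not bias their own
        local mean.
    adaptive_offset
        Subtracted from the local mean before comparison (intensity units).
    canny_sigma, canny_thresholds
        Gaussian scale (px) and (low, high) hysteresis fractions of the
        Canny boundary detector.
    closing_radius
        Disk radius (px) of the morphological closing that heals boundary
        pixels flipped by the XOR combination.
    min_hole_area, min_object_area
        Area cutoffs in px^2 for hole filling and speckle removal.
    log_min_sigma, log_max_sigma, log_threshold
        Scale range (px) and relative response threshold of the
        Laplacian-of-Gaussian small-object detector merged in last.
    min_contrast_snr
        Labeled objects whose mean intensity differs from the background
        by less than this multiple of the estimated noise are discarded
        (rejects noise-only structure on featureless frames; 0 disables).
    background_correction
        'polynomial_fit' (robust low-order surface) or 'rolling_ball'.
    background_scale
        Polynomial order, or rolling-ball radius in px.
    background_mode
        'divide' (multiplicative illumination) or 'subtract'.
    """

    adaptive_block_size: int = 101
    adaptive_offset: float = 0.0
    canny_sigma: float = 1.0
    canny_thresholds: tuple = (0.1, 0.3)
    closing_radius: int = 1
    min_hole_area: int = 9
    min_object_area: int = 9
    log_min_sigma: float = 1.5
    log_max_sigma: float = 4.0
    log_threshold: float = 0.1
    min_contrast_snr: float = 3.0
    background_correction: str = "polynomial_fit"
    background_scale: float = 2
    background_mode: str = "divide"

    def __post_init__(self):
        if self.adaptive_block_size < 3 or self.adaptive_block_size % 2 == 0:
            raise ValueError("adaptive_block_size must be odd and >= 3")
        low, high = self.canny_thresholds
        if not low < high:
            raise ValueError("canny low threshold must be below high")
        if self.log_min_sigma > self.log_max_sigma:
            raise ValueError("log_min_sigma must be <= log_max_sigma")
        for name in ("closing_radius", "min_hole_area", "min_object_area"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.background_correction not in ("polynomial_fit", "rolling_ball"):
            raise ValueError(f"unknown background_correction {self.background_correction!r}")
        if self.background_mode not in ("divide", "subtract"):
            raise ValueError(f"unknown background_mode {self.background_mode!r}")


@dataclass
class LabeledDomains:
    """Per-frame segmentation result.

    mask
        Binary mask; True marks the bright phase (Ld for a DiD-labeled
        membrane under default semantics).
    labels
        Connected-component label image of ``mask`` (0 = background).
    regions
        DataFrame with one row per label: area_um2, perimeter_um,
        x_um, y_um (centroid), phase ('Lo'/'Ld').
    """

    frame_index: int
    mask: np.ndarray
    labels: np.ndarray
    regions: pd.DataFrame
    pixel_size_um: float
    bright_phase: str = "Ld"

    @property
    def n_domains(self) -> int:
        return int(self.labels.max())


def _polynomial_surface(frame: np.ndarray, order: int) -> np.ndarray:
    """Low-order polynomial illumination estimate from the majority phase.

    Both lipid phases are modulated by the same multiplicative illumination
    field, so the surface can be estimated from either one alone.  Pixels
    are split at the Otsu threshold, the surface is fitted by least squares
    to the more abundant class (usually the continuous phase), and one
    outlier-rejection pass removes stragglers of the other class.  Fitting
    one phase avoids the strong bias a whole-frame fit picks up from the
    foreground domains.
    """
    if np.ptp(frame) == 0:
        return np.full_like(frame, frame.flat[0])
    h, w = frame.shape
    yy, xx = np.meshgrid(np.linspace(-1, 1, h), np.linspace(-1, 1, w), indexing="ij")
    cols = [np.ones_like(xx)]
    for total in range(1, int(order) + 1):
        for i in range(total + 1):
            cols.append(xx ** (total - i) * yy ** i)
    design = np.column_stack([c.ravel() for c in cols])
    z = frame.ravel()
    above = z > filters.threshold_otsu(frame)
    keep = above if above.sum() > z.size / 2 else ~above
    coef = None
    for _ in range(2):
        coef, *_ = np.linalg.lstsq(design[keep], z[keep], rcond=None)
        resid = z - design @ coef
        med = np.median(resid[keep])
        scale = 1.4826 * np.median(np.abs(resid[keep] - med))
        if scale <= 0:
            break
        refined = keep & (np.abs(resid - med) < 3.0 * scale)
        if refined.sum() < design.shape[1] * 3:
            break
        keep = refined
    return (design @ coef).reshape(frame.shape)


def correct_background(frame: np.ndarray,
                       params: SegmentationParams = SegmentationParams()) -> np.ndarray:
    """Remove the uneven illumination background from one frame.

    In 'divide' mode the frame is divided by the estimated surface scaled
    to unit mean (multiplicative illumination model); in 'subtract' mode
    the zero-mean surface is subtracted.  Either way the output mean equals
    the input mean.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    bad = ~np.isfinite(frame)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(f"frame contains a non-finite pixel at (row={r}, col={c})")
    if np.all(frame == 0):
        raise ValueError("frame is identically zero; no background surface estimable")

    if params.background_correction == "polynomial_fit":
        surface = _polynomial_surface(frame, int(params.background_scale))
    else:
        from skimage.restoration import rolling_ball
        surface = rolling_ball(frame, radius=float(params.background_scale))
        surface = filters.gaussian(surface, sigma=max(params.background_scale / 4, 1))

    if params.background_mode == "divide":
        mean = surface.mean()
        if mean == 0 or np.any(surface * np.sign(mean) <= 0):
            # surface crosses zero; division unsafe, fall back to subtraction
            return frame - surface + frame.mean()
        out = frame / (surface / mean)
        out_mean = out.mean()
        return out * (frame.mean() / out_mean) if out_mean != 0 else out
    return frame - surface + surface.mean()


def _adaptive_threshold(frame: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Local adaptive threshold with a global fallback in flat regions.

    Comparing a pixel against its local mean is only informative where the
    two differ by more than the noise; deep inside one phase (or in
    background far from any domain) the difference is pure noise and the
    local comparison degenerates into coin-flipping.  Such pixels are
    classified by the global Otsu threshold instead, which also resolves
    exact ties on noiseless frames.
    """
    from scipy.ndimage import gaussian_filter
    from skimage.restoration import estimate_sigma

    block = min(params.adaptive_block_size, _largest_odd(min(frame.shape)))
    # Gaussian-weighted local mean, the 'gaussian' mode of local thresholding
    sigma = (block - 1) / 6.0
    local = gaussian_filter(frame, sigma, mode="reflect") - params.adaptive_offset
    global_t = filters.threshold_otsu(frame)
    noise = float(estimate_sigma(frame))
    if not np.isfinite(noise):
        noise = 0.0
    # the epsilon keeps the band non-empty on noiseless frames, where
    # floating-point jitter would otherwise reintroduce threshold ties
    band = 3.0 * noise + 1e-6 * np.ptp(frame)
    uncertain = np.abs(frame - local) <= band
    return np.where(uncertain, frame > global_t, frame > local)


def _reject_low_contrast(frame: np.ndarray, mask: np.ndarray,
                         params: SegmentationParams) -> np.ndarray:
    """Drop labeled objects indistinguishable from background noise.

    An object is kept when its mean intensity differs from the mean of the
    unmasked background by at least ``min_contrast_snr`` times the estimated
    per-pixel noise.  On a featureless noise-only frame this removes every
    spurious component, so blank frames yield zero labels.
    """
    if params.min_contrast_snr <= 0 or not mask.any() or mask.all():
        return mask
    from skimage.restoration import estimate_sigma

    sigma = float(estimate_sigma(frame))
    if sigma == 0 or not np.isfinite(sigma):
        return mask
    bg_mean = frame[~mask].mean()
    labels = measure.label(mask, connectivity=2)
    keep = np.zeros(labels.max() + 1, dtype=bool)
    for p in measure.regionprops(labels, intensity_image=frame):
        contrast = abs(p.intensity_mean - bg_mean)
        keep[p.label] = contrast >= params.min_contrast_snr * sigma
    return keep[labels]


def _log_small_objects(frame: np.ndarray, params: SegmentationParams,
                       existing: np.ndarray) -> np.ndarray:
    """Mask of small bright blobs missed by the threshold stage.

    Multiscale LoG detections whose footprint intersects the existing mask
    are skipped: the merge can only rescue small objects the thresholding
    lost, never modify objects already present (so disabling it never
    increases the object count).
    """
    rng = np.ptp(frame)
    if rng == 0:
        return np.zeros(frame.shape, dtype=bool)
    img = (frame - frame.min()) / rng
    blobs = feature.blob_log(img, min_sigma=params.log_min_sigma,
                             max_sigma=params.log_max_sigma, num_sigma=5,
                             threshold=params.log_threshold)
    mask = np.zeros(frame.shape, dtype=bool)
    if len(blobs):
        yy, xx = np.mgrid[0:frame.shape[0], 0:frame.shape[1]]
        for r, c, sigma in blobs:
            rad = np.sqrt(2.0) * sigma
            disk = (yy - r) ** 2 + (xx - c) ** 2 <= rad**2
            if not (existing & disk).any():
                mask |= disk
    return mask


def segment_frame(frame: np.ndarray, params: SegmentationParams = SegmentationParams(),
                  pixel_size_um: float = 1.0, frame_index: int = 0,
                  include_log_merge: bool = True) -> LabeledDomains:
    """Segment one background-corrected membrane frame into labeled domains.

    Stages, in order: local adaptive threshold -> Canny boundary map ->
    XOR combination -> morphological closing -> hole removal -> LoG
    small-object merge -> speckle removal -> connected-component labeling.
    A featureless frame yields zero labels without error.

    ``include_log_merge=False`` disables the final LoG merge (useful to
    examine what that stage contributes).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")

    if np.ptp(frame) == 0:
        mask = np.zeros(frame.shape, dtype=bool)
    else:
        thresh_mask = _adaptive_threshold(frame, params)
        low, high = params.canny_thresholds
        edges = feature.canny(frame, sigma=params.canny_sigma,
                              low_threshold=low, high_threshold=high,
                              use_quantiles=False)
        # XOR combination: along detected boundaries, pixels where the
        # local-adaptive and global-intensity classifications disagree are
        # flipped toward the intensity class.  Boundary pixels the local
        # threshold lost are restored, spurious ones removed; on a clean
        # mask the disagreement band is empty and the stage is a no-op.
        bright = frame > filters.threshold_otsu(frame)
        combined = thresh_mask ^ (edges & (thresh_mask ^ bright))
        if params.closing_radius > 0:
            combined = morphology.closing(
                combined, morphology.disk(params.closing_radius))
        if params.min_hole_area > 0:
            mask = morphology.remove_small_holes(
                combined, max_size=params.min_hole_area - 1)
        else:
            mask = combined
        if include_log_merge:
            mask = mask | _log_small_objects(frame, params, existing=mask)
        if params.min_object_area > 0:
            mask = morphology.remove_small_objects(
                mask, max_size=params.min_object_area - 1)
        mask = _reject_low_contrast(frame, mask, params)

    labels = measure.label(mask, connectivity=2)
    regions = _measure_regions(labels, pixel_size_um)
    return LabeledDomains(frame_index=frame_index, mask=mask, labels=labels,
                          regions=regions, pixel_size_um=pixel_size_um)


def _largest_odd(n: int) -> int:
    return n if n % 2 == 1 else n - 1


def _measure_regions(labels: np.ndarray, pixel_size_um: float) -> pd.DataFrame:
    props = measure.regionprops(labels)
    rows = []
    for p in props:
        cy, cx = p.centroid  # (row, col)
        rows.append({
            "label": p.label,
            "area_um2": p.area * pixel_size_um**2,
            "perimeter_um": p.perimeter_crofton * pixel_size_um,
            "x_um": cx * pixel_size_um,
            "y_um": cy * pixel_size_um,
            "phase": "Ld",
        })
    return pd.DataFrame(rows, columns=["label", "area_um2", "perimeter_um",
                                       "x_um", "y_um", "phase"])


def assign_phase(domains: LabeledDomains,
                 channel_semantics: str = "bright_is_Ld") -> LabeledDomains:
    """Tag labeled objects with their lipid phase.

    ``bright_is_Ld`` (DiD-labeled bilayers: the dye partitions to the Ld
    phase) tags mask objects Ld and the dark complement Lo;
    ``bright_is_Lo`` inverts the assignment (e.g. monolayer mixtures where
    the labeled phase is the expanded one and domains are condensed).
    """
    if channel_semantics == "bright_is_Ld":
        bright = "Ld"
    elif channel_semantics == "bright_is_Lo":
        bright = "Lo"
    else:
        raise ValueError(f"unknown channel_semantics {channel_semantics!r}")
    regions = domains.regions.copy()
    if len(regions):
        regions["phase"] = bright
    domains.regions = regions
    domains.bright_phase = bright
    return domains


def phase_areas(domains: LabeledDomains) -> dict:
    """Total area per phase in um^2; the dark phase is the mask complement."""
    px2 = domains.pixel_size_um**2
    bright_area = float(domains.mask.sum()) * px2
    total = domains.mask.size * px2
    dark = "Lo" if domains.bright_phase == "Ld" else "Ld"
    return {domains.bright_phase: bright_area, dark: total - bright_area}


def segment_sequence(frames: np.ndarray, params: SegmentationParams = SegmentationParams(),
                     pixel_size_um: float = 1.0,
                     channel_semantics: str = "bright_is_Ld",
                     correct: bool = True) -> list:
    """Background-correct, segment and phase-tag every frame of a stack."""
    out = []
    for i, frame in enumerate(np.asarray(frames, dtype=float)):
        corrected = correct_background(frame, params) if correct else frame
        dom = segment_frame(corrected, params, pixel_size_um=pixel_size_um,
                            frame_index=i)
        out.append(assign_phase(dom, channel_semantics))
    return out
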