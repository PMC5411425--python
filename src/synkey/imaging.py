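"""Image-based postural-synergy verification.

Pipeline: chroma-key the hand against a uniform green background, keep the
largest connected component and fill holes, crop at the wrist, compute the
silhouette centroid, trace the boundary and keep the digit-edge region (the
upward half-plane from the centroid), and express it as a *radial profile*:
centroid-to-boundary distances sampled on a fixed angular grid and divided
by the minimum retained distance, so the profile's minimum is exactly 1.0
and the representation is invariant to translation and uniform scale.

Binarization plus normalization deliberately discard skin colour, texture,
and absolute hand size; what remains is the relative posture.

The profile is split into five per-finger segments at the valleys between
the five most prominent peaks (the fingertips).  The number of angular
samples per finger is *not* fixed — it shrinks with less abduction or more
flexion — and the per-finger Euclidean error zero-pads the shorter segment,
so point-count differences inflate the error by design.  The total error
over the five fingers is compared against the posture threshold ``T_p``
(accept iff total < T_p, strictly).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from skimage import color, measure

from .errors import FingerDetectionError, InvalidInputError, SegmentationError
from .joints import DIGITS

logger = logging.getLogger(__name__)


@dataclass
class ImagingConfig:
    """Tunable imaging parameters (defaults tuned on the built-in renderer)."""

    #: HSV hue window treated as background (green ~ 1/3).
    green_hue: tuple[float, float] = (0.20, 0.47)
    #: Minimum saturation for a pixel to count as keyed background.
    min_saturation: float = 0.25
    #: Fraction of the component height scanned for the wrist neck.
    wrist_fraction: float = 0.25
    #: Fixed wrist-crop row override (image row index), or None to detect.
    wrist_row: int | None = None
    #: Number of equal arc-length samples of the digit-edge outline (the
    #: split into fingers at the valleys is what varies between postures).
    profile_samples: int = 100
    #: Distances are quantized to this resolution before valley placement so
    #: that flat valley bottoms split deterministically (first-index tie).
    valley_quantum: float = 0.005
    #: Angular margin excluded at each end of the digit region (degrees);
    #: boundary points close to horizontal belong to the palm sides.
    angle_margin_deg: float = 5.0
    #: Peak prominence floor for fingertip detection (normalized distance units).
    peak_prominence: float = 0.3
    #: Boundary regularization scale, as a fraction of the square root of
    #: the silhouette area (scale-free).  The traced contour is Gaussian
    #: smoothed at this world scale before arc lengths and distances are
    #: measured, so they do not depend on the pixel grid.
    boundary_smooth_frac: float = 0.03
    #: Reject images whose principal axis tilts more than this from vertical
    #: (degrees); None disables the check (the capture rig fixes orientation).
    max_tilt_deg: float | None = None


@dataclass
class HandMask:
    """Binary hand silhouette (True = hand), image row 0 at the top.

    ``intensity`` optionally carries the continuous foreground-coverage map
    (1 = hand, 0 = background) restricted to the kept component; when
    present, boundary tracing uses its 0.5 level for subpixel edge accuracy
    (antialiased edges carry the subpixel position the binary mask loses).
    """

    mask: np.ndarray
    wrist_row: int | None = None
    intensity: np.ndarray | None = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise InvalidInputError("mask must be 2-D")
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=float)
            if self.intensity.shape != self.mask.shape:
                raise InvalidInputError("intensity must match the mask shape")


@dataclass
class RadialProfile:
    """Digit-edge distances from the centroid, normalized so min == 1.0."""

    angles_deg: np.ndarray  # bin centres, descending from thumb to pinky side
    distances: np.ndarray  # normalized distances, same length
    centroid: tuple[float, float]  # (row, col)

    def __post_init__(self):
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.angles_deg.shape != self.distances.shape:
            raise InvalidInputError("angles and distances must align")


@dataclass
class FingerSegment:
    label: str  # thumb..pinky
    values: np.ndarray  # normalized distances
    angles_deg: np.ndarray

    @property
    def point_count(self) -> int:
        return int(self.values.size)


@dataclass
class PostureScore:
    per_finger: dict[str, float] | None
    total: float
    threshold: float
    accepted: bool
    reason: str | None = None


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_hand(image: np.ndarray, config: ImagingConfig | None = None) -> HandMask:
    """Chroma-key segmentation: remove green background, keep the hand.

    Keeps the largest connected foreground component and fills holes.
    """
    config = config or ImagingConfig()
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] < 3:
        raise InvalidInputError("expected an RGB image (H, W, 3)")
    hsv = color.rgb2hsv(image[:, :, :3])
    lo, hi = config.green_hue
    background = (
        (hsv[:, :, 0] >= lo)
        & (hsv[:, :, 0] <= hi)
        & (hsv[:, :, 1] >= config.min_saturation)
    )
    foreground = ~background
    labels, n = ndimage.label(foreground)
    if n == 0:
        raise SegmentationError("no foreground component found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    mask = labels == (int(np.argmax(sizes)) + 1)
    mask = ndimage.binary_fill_holes(mask)
    if config.max_tilt_deg is not None:
        tilt = _principal_axis_tilt(mask)
        if tilt > config.max_tilt_deg:
            raise SegmentationError(
                f"hand tilted {tilt:.1f} deg from vertical (max {config.max_tilt_deg})"
            )
    # Continuous foreground coverage from the red channel (the keyed green
    # background has no red; antialiased silhouette edges blend linearly),
    # restricted to the kept component's neighbourhood.
    intensity = image[:, :, 0].astype(float) / 255.0
    intensity *= ndimage.binary_dilation(mask, iterations=2)
    return HandMask(mask=mask, intensity=intensity)


def _principal_axis_tilt(mask: np.ndarray) -> float:
    """Angle (degrees) of the silhouette's principal axis from vertical."""
    props = measure.regionprops(mask.astype(int))[0]
    # regionprops orientation: angle between the major axis and the row axis.
    return abs(np.degrees(props.orientation))


def crop_wrist(hand: HandMask, config: ImagingConfig | None = None) -> HandMask:
    """Remove rows at/below the wrist neck.

    The wrist line is the narrowest row in the lower ``wrist_fraction`` of the
    component, accepted only if some row below it is wider (a genuine neck);
    otherwise the mask is assumed already cropped and returned unchanged.
    A ``wrist_row`` override in the config crops at that row uncondionally.
    """
    config = config or ImagingConfig()
    mask = hand.mask.copy()
    rows = np.flatnonzero(mask.any(axis=1))
    if rows.size == 0:
        raise SegmentationError("empty mask")
    r0, r1 = int(rows[0]), int(rows[-1])

    def _cropped(crop_at: int | None) -> HandMask:
        intensity = None if hand.intensity is None else hand.intensity.copy()
        if crop_at is not None:
            mask[crop_at:] = False
            if intensity is not None:
                intensity[crop_at:] = 0.0
            if not mask.any():
                raise SegmentationError("wrist crop removed the whole hand")
        return HandMask(
            mask=mask,
            wrist_row=crop_at if crop_at is not None else hand.wrist_row,
            intensity=intensity,
        )

    if config.wrist_row is not None:
        return _cropped(int(config.wrist_row))
    widths = mask.sum(axis=1)
    region_start = r1 - int(config.wrist_fraction * (r1 - r0))
    region = np.arange(region_start, r1 + 1)
    region = region[widths[region] > 0]
    if region.size == 0:
        return _cropped(None)
    neck = int(region[int(np.argmin(widths[region]))])
    below = np.arange(neck + 1, r1 + 1)
    if below.size == 0 or not np.any(widths[below] > widths[neck]):
        logger.debug("no wrist neck found; mask treated as already cropped")
        return _cropped(None)
    return _cropped(neck)


def centroid(hand: HandMask | np.ndarray) -> tuple[float, float]:
    """Arithmetic mean (row, col) of the foreground pixels.

    When the mask carries a coverage map, edge pixels are weighted by their
    foreground fraction, which keeps the centroid consistent across image
    resolutions.
    """
    if isinstance(hand, HandMask) and hand.intensity is not None:
        w = hand.intensity
        total = float(w.sum())
        if total == 0:
            raise SegmentationError("empty mask has no centroid")
        rows = np.arange(w.shape[0])[:, None]
        cols = np.arange(w.shape[1])[None, :]
        return (float((w * rows).sum() / total), float((w * cols).sum() / total))
    mask = hand.mask if isinstance(hand, HandMask) else np.asarray(hand, dtype=bool)
    if not mask.any():
        raise SegmentationError("empty mask has no centroid")
    rows, cols = np.nonzero(mask)
    return (float(rows.mean()), float(cols.mean()))


# ---------------------------------------------------------------------------
# Radial profile
# ---------------------------------------------------------------------------

def digit_outline(
    hand: HandMask,
    center: tuple[float, float] | None = None,
    config: ImagingConfig | None = None,
) -> RadialProfile:
    """Centroid-normalized outline profile of the digit-edge region.

    The silhouette boundary is traced as an ordered subpixel contour; the
    digit-edge region is the contiguous boundary arc in the upward
    half-plane from the centroid (a small angular margin off the horizontal
    excludes the palm sides).  Centroid distances along that arc are
    resampled at ``profile_samples`` equal arc-length steps and divided by
    their minimum — the profile minimum is exactly 1.0 and the
    representation is invariant to translation and uniform scale.  How many
    of the samples each *finger* receives is not fixed: the split at the
    valleys moves with abduction and flexion, so a narrower or less flexed
    finger claims fewer points.  Samples run from the thumb side to the
    pinky side.
    """
    config = config or ImagingConfig()
    center = center or centroid(hand)
    field = hand.intensity if hand.intensity is not None else hand.mask.astype(float)
    contours = measure.find_contours(field, 0.5)
    if not contours:
        raise SegmentationError("no boundary found")
    contour = max(contours, key=len)
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    if config.boundary_smooth_frac > 0:
        sigma_px = config.boundary_smooth_frac * float(np.sqrt(hand.mask.sum()))
        spacing = float(
            np.mean(np.linalg.norm(np.diff(contour, axis=0), axis=1))
        )
        contour = ndimage.gaussian_filter1d(
            contour, sigma_px / max(spacing, 1e-9), axis=0, mode="wrap"
        )
    y = center[0] - contour[:, 0]  # up-positive
    x = contour[:, 1] - center[1]
    ang = np.degrees(np.arctan2(y, x))
    margin = config.angle_margin_deg
    keep = (y > 0) & (ang >= margin) & (ang <= 180.0 - margin)
    if not np.any(keep):
        raise SegmentationError("empty digit region above the centroid")
    run = _longest_cyclic_run(keep)
    pts = contour[run]
    pts_ang = ang[run]
    if pts_ang[0] < pts_ang[-1]:  # orient thumb (large angle) first
        pts = pts[::-1]
        pts_ang = pts_ang[::-1]
        run = run[::-1]
    # Refine both endpoints to the exact margin-angle crossing so the arc
    # parametrization starts at the same world point at any resolution.
    n_pts = contour.shape[0]
    prev_idx = (run[0] + (run[0] - run[1])) % n_pts if run.size > 1 else run[0]
    next_idx = (run[-1] + (run[-1] - run[-2])) % n_pts if run.size > 1 else run[-1]
    head_pt = _margin_crossing(contour, ang, prev_idx, run[0], 180.0 - margin)
    tail_pt = _margin_crossing(contour, ang, next_idx, run[-1], margin)
    if head_pt is not None:
        pts = np.vstack([head_pt, pts])
        pts_ang = np.concatenate([[180.0 - margin], pts_ang])
    if tail_pt is not None:
        pts = np.vstack([pts, tail_pt])
        pts_ang = np.concatenate([pts_ang, [margin]])
    y_run = center[0] - pts[:, 0]
    x_run = pts[:, 1] - center[1]
    dists = np.hypot(x_run, y_run)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if arc[-1] <= 0 or dists.min() <= 0:
        raise SegmentationError("degenerate boundary at the centroid")
    n = config.profile_samples
    step = arc[-1] / n
    # Valley-anchored resampling: fingertip peaks and the valleys between
    # them are located on the dense boundary polyline, and each stretch
    # between consecutive valleys is sampled uniformly starting exactly at
    # its valley.  Valleys are therefore always sample points, so the
    # discrete finger split cannot straddle a valley bottom, while the
    # number of samples a finger receives still tracks its outline length.
    anchors = _valley_anchors(arc, dists / dists.min(), config)
    bounds = [0.0] + anchors + [float(arc[-1])]
    grid_parts = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        count = max(1, int(round((hi - lo) / step)))
        grid_parts.append(lo + np.arange(count) * ((hi - lo) / count))
    grid = np.concatenate(grid_parts)
    sampled = np.interp(grid, arc, dists)
    sampled_ang = np.interp(grid, arc, pts_ang)
    return RadialProfile(
        angles_deg=sampled_ang,
        distances=sampled / sampled.min(),
        centroid=center,
    )


def _valley_anchors(
    arc: np.ndarray, normalized: np.ndarray, config: "ImagingConfig"
) -> list[float]:
    """Arc positions of the valleys between the five most prominent peaks.

    Each valley is refined to sub-vertex precision by a parabolic fit around
    the discrete minimum, which keeps the anchor stable against vertex-level
    measurement noise.  Returns an empty list when fewer than five peaks
    exist; the resampling then falls back to a single uniform stretch and
    the finger split will report the shortfall.
    """
    peaks, props = find_peaks(normalized, prominence=config.peak_prominence)
    if peaks.size < 5:
        return []
    top5 = np.sort(peaks[np.argsort(-props["prominences"])[:5]])
    anchors = []
    for a, b in zip(top5[:-1], top5[1:]):
        v = int(a + np.argmin(normalized[a : b + 1]))
        lo = max(a, v - 6)
        hi = min(b, v + 6)
        window = slice(lo, hi + 1)
        if hi - lo >= 2:
            coeff = np.polyfit(arc[window], normalized[window], 2)
            if coeff[0] > 0:
                s_star = float(-coeff[1] / (2 * coeff[0]))
                s_star = min(max(s_star, float(arc[lo])), float(arc[hi]))
            else:
                s_star = float(arc[v])
        else:
            s_star = float(arc[v])
        anchors.append(s_star)
    return anchors


def _margin_crossing(
    contour: np.ndarray, ang: np.ndarray, i_out: int, i_in: int, target: float
) -> np.ndarray | None:
    """Interpolated contour point where the boundary crosses a margin angle."""
    a0, a1 = ang[i_out], ang[i_in]
    if a0 == a1 or i_out == i_in:
        return None
    t = (target - a0) / (a1 - a0)
    if not 0.0 < t < 1.0:
        return None
    return contour[i_out] + t * (contour[i_in] - contour[i_out])


def _longest_cyclic_run(keep: np.ndarray) -> np.ndarray:
    """Indices of the longest contiguous True run on a cyclic sequence."""
    n = keep.size
    if keep.all():
        return np.arange(n)
    doubled = np.concatenate([keep, keep])
    best_start, best_len, cur_start, cur_len = 0, 0, None, 0
    for i, flag in enumerate(doubled):
        if flag:
            if cur_start is None:
                cur_start = i
            cur_len += 1
            if cur_len > best_len and cur_start < n:
                best_start, best_len = cur_start, cur_len
        else:
            cur_start, cur_len = None, 0
    best_len = min(best_len, n)
    return np.arange(best_start, best_start + best_len) % n


def split_fingers(
    profile: RadialProfile, config: ImagingConfig | None = None
) -> list[FingerSegment]:
    """Split the radial profile into five finger segments at the valleys.

    The five most prominent peaks are taken as fingertips (thumb to pinky in
    profile order); segment boundaries sit at the minimum between consecutive
    peaks and at the profile ends.  Fewer than five detectable peaks — for
    example a finger folded out of the silhouette — raises
    :class:`FingerDetectionError` carrying the detected count.
    """
    config = config or ImagingConfig()
    d = profile.distances
    peaks, props = find_peaks(d, prominence=config.peak_prominence)
    if peaks.size < 5:
        raise FingerDetectionError(int(peaks.size))
    top5 = peaks[np.argsort(-props["prominences"])[:5]]
    top5 = np.sort(top5)
    # Valleys on lightly quantized values: flat web bottoms then split at the
    # same sample regardless of sub-quantum measurement noise.
    dq = np.round(d / config.valley_quantum) * config.valley_quantum
    boundaries = [0]
    for a, b in zip(top5[:-1], top5[1:]):
        boundaries.append(int(a + np.argmin(dq[a : b + 1])))
    boundaries.append(d.size)
    segments = []
    for label, lo, hi in zip(DIGITS, boundaries[:-1], boundaries[1:]):
        segments.append(
            FingerSegment(
                label=label,
                values=d[lo:hi].copy(),
                angles_deg=profile.angles_deg[lo:hi].copy(),
            )
        )
    return segments


def finger_error(template: FingerSegment, entry: FingerSegment) -> float:
    """Euclidean error between two finger outlines.

    The shorter sequence is zero-padded at the tail to the longer length, so
    differing point counts (less abduction or flexion) inflate the error.
    """
    if template.label != entry.label:
        raise InvalidInputError(
            f"finger label mismatch: {template.label} vs {entry.label}"
        )
    n = max(template.point_count, entry.point_count)
    a = np.zeros(n)
    b = np.zeros(n)
    a[: template.point_count] = template.values
    b[: entry.point_count] = entry.values
    return float(np.linalg.norm(a - b))


# ---------------------------------------------------------------------------
# Verification
# ---------------------------------------------------------------------------

def analyze_image(
    image: np.ndarray, config: ImagingConfig | None = None
) -> list[FingerSegment]:
    """Full image pipeline: segmentation -> crop -> profile -> finger split."""
    config = config or ImagingConfig()
    hand = crop_wrist(segment_hand(image, config), config)
    profile = digit_outline(hand, config=config)
    return split_fingers(profile, config)


def posture_verify(
    template_image: np.ndarray,
    entry_image: np.ndarray,
    T_p: float,
    config: ImagingConfig | None = None,
) -> PostureScore:
    """Accept iff the summed per-finger error is strictly below ``T_p``.

    Finger-detection failures reject the attempt with the failure as reason.
    """
    try:
        template_fingers = analyze_image(template_image, config)
        entry_fingers = analyze_image(entry_image, config)
    except (FingerDetectionError, SegmentationError) as err:
        return PostureScore(
            per_finger=None,
            total=float("inf"),
            threshold=T_p,
            accepted=False,
            reason=str(err),
        )
    per_finger = {
        t.label: finger_error(t, e)
        for t, e in zip(template_fingers, entry_fingers)
    }
    total = float(sum(per_finger.values()))
    return PostureScore(
        per_finger=per_finger,
        total=total,
        threshold=T_p,
        accepted=bool(total < T_p),
    )


# ---------------------------------------------------------------------------
# Best-posture selection
# ---------------------------------------------------------------------------

@dataclass
class BestPostures:
    selected: list[int]  # posture indices, least authentic error first
    combined_eer: float
    combined_threshold: float  # on the max-error scale


def best_postures(
    true_errors: dict[int, np.ndarray],
    false_errors: dict[int, np.ndarray],
    k: int,
) -> BestPostures:
    """Select the ``k`` postures with least mean authentic error.

    The combined decision requires every selected posture to pass, i.e. the
    per-attempt score is the maximum error over the selected postures
    (attempts must be aligned across postures).  The combined EER is computed
    on negated max-errors so the standard accept-if-greater rule applies.
    """
    from .evaluation import compute_eer

    if k < 1 or k > len(true_errors):
        raise InvalidInputError(f"k must be in 1..{len(true_errors)}")
    ranked = sorted(true_errors, key=lambda p: float(np.mean(true_errors[p])))
    selected = ranked[:k]
    true_max = np.max(np.stack([np.asarray(true_errors[p], dtype=float) for p in selected]), axis=0)
    false_max = np.max(np.stack([np.asarray(false_errors[p], dtype=float) for p in selected]), axis=0)
    result = compute_eer(-true_max, -false_max)
    return BestPostures(
        selected=selected,
        combined_eer=result.eer,
        combined_threshold=-result.eer_threshold,
    )
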