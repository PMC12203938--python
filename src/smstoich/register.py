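"""Stack correction, channel registration, spot detection and trajectory
extraction.

Detection uses difference-of-Gaussians maxima on an average of the first
frames (molecules are brightest before bleaching) with sub-pixel centroid
or Gaussian-fit refinement; the inter-channel transform is a least-squares
fit over mutual-nearest-neighbour matched bead centroids; photometry is a
circular aperture minus an annulus-median background.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.distance import cdist
from skimage import transform as sktransform
from skimage.feature import peak_local_max

from .errors import (
    BorderExclusionError,
    DimensionError,
    InvalidParameterError,
    RegistrationError,
)
from .types import ChannelTransform, Spot, Trajectory, as_xy_array

MIN_BEADS = {"translation": 1, "similarity": 2, "affine": 3}


# --------------------------------------------------------------------------
# stack correction


def correct_stack(
    stack: np.ndarray,
    dark_offset: float = 0.0,
    flatfield: np.ndarray | None = None,
) -> np.ndarray:
    """Offset/flat-field correction: ``(stack - dark_offset) / flatfield``,
    clipped at zero.  A no-op when offset is 0 and no flat field is given."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise DimensionError(f"stack must be 2-D or 3-D, got shape {stack.shape}")
    out = stack - dark_offset
    if flatfield is not None:
        flatfield = np.asarray(flatfield, dtype=float)
        if flatfield.shape != stack.shape[1:]:
            raise DimensionError(
                f"flat-field shape {flatfield.shape} != frame shape {stack.shape[1:]}"
            )
        if np.any(flatfield <= 0):
            raise InvalidParameterError("flat-field map must be strictly positive")
        out = out / flatfield
    return np.clip(out, 0.0, None)


# --------------------------------------------------------------------------
# sub-pixel refinement


def _refine_centroid(
    img: np.ndarray, peak_rc: tuple[int, int], radius: int = 3
) -> tuple[float, float]:
    """Background-subtracted intensity-weighted centroid in a square window.

    Returns (x, y).  The local background is the window-border median.
    """
    h, w = img.shape
    r, c = peak_rc
    r0, r1 = max(0, r - radius), min(h, r + radius + 1)
    c0, c1 = max(0, c - radius), min(w, c + radius + 1)
    win = img[r0:r1, c0:c1].astype(float)
    border = np.concatenate([win[0], win[-1], win[1:-1, 0], win[1:-1, -1]])
    wgt = np.clip(win - np.median(border), 0.0, None)
    tot = wgt.sum()
    if tot <= 0:
        return float(c) + 0.5, float(r) + 0.5
    ys, xs = np.mgrid[r0:r1, c0:c1]
    # +0.5: pixel (0,0) spans [0,1)^2, so its centre is (0.5, 0.5)
    x = float((wgt * (xs + 0.5)).sum() / tot)
    y = float((wgt * (ys + 0.5)).sum() / tot)
    return x, y


def _refine_gaussian(
    img: np.ndarray, peak_rc: tuple[int, int], sigma0: float = 1.2, radius: int = 5
) -> tuple[float, float]:
    """Least-squares 2-D Gaussian fit in a local window; falls back to the
    centroid on failure.  Returns (x, y)."""
    h, w = img.shape
    r, c = peak_rc
    r0, r1 = max(0, r - radius), min(h, r + radius + 1)
    c0, c1 = max(0, c - radius), min(w, c + radius + 1)
    win = img[r0:r1, c0:c1].astype(float)
    ys, xs = np.mgrid[r0:r1, c0:c1]
    x0, y0 = _refine_centroid(img, peak_rc, radius=min(radius, 3))
    bg0 = float(np.median(win))
    amp0 = float(win.max() - bg0)

    def model(p):
        amp, x, y, s, bg = p
        return bg + amp * np.exp(-(((xs + 0.5 - x) ** 2 + (ys + 0.5 - y) ** 2) / (2 * s**2)))

    def resid(p):
        return (model(p) - win).ravel()

    try:
        res = optimize.least_squares(
            resid,
            x0=[amp0, x0, y0, sigma0, bg0],
            bounds=([0, c0, r0, 0.3, -np.inf], [np.inf, c1, r1, radius, np.inf]),
            max_nfev=200,
        )
        return float(res.x[1]), float(res.x[2])
    except Exception:
        return x0, y0


# --------------------------------------------------------------------------
# spot detection


def detect_spots(
    stack: np.ndarray,
    detect_frames: int = 10,
    min_sigma: float = 1.0,
    max_sigma: float = 2.0,
    threshold_nsigma: float = 5.0,
    threshold: float | None = None,
    merge_radius_px: float = 3.0,
    channel: str = "",
    field_id: str = "",
    refine: str = "centroid",
) -> list[Spot]:
    """Detect fluorescent spots on the average of the first ``detect_frames``
    frames.

    A difference-of-Gaussians band pass suppresses background structure;
    candidate maxima above ``threshold`` (default: ``threshold_nsigma`` times
    the robust noise SD of the filtered image) are refined to sub-pixel
    centres, and duplicates within ``merge_radius_px`` collapse to the
    brighter one.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3 or stack.size == 0:
        raise DimensionError(f"empty or non-3-D stack, shape {stack.shape}")
    detect_frames = min(detect_frames, stack.shape[0])
    img = stack[:detect_frames].mean(axis=0)

    dog = ndimage.gaussian_filter(img, min_sigma) - ndimage.gaussian_filter(img, max_sigma)
    if threshold is None:
        mad = np.median(np.abs(dog - np.median(dog)))
        threshold = threshold_nsigma * 1.4826 * mad
    peaks = peak_local_max(
        dog, min_distance=2, threshold_abs=threshold, exclude_border=2
    )

    refiner = _refine_gaussian if refine == "gaussian" else _refine_centroid
    spots: list[Spot] = []
    for r, c in peaks:
        x, y = refiner(img, (int(r), int(c)))
        spots.append(
            Spot(
                x=x,
                y=y,
                channel=channel,
                field_id=field_id,
                peak_intensity=float(img[r, c]),
                detect_frames=(0, detect_frames),
            )
        )

    # collapse duplicates closer than the merge radius, keeping the brighter
    spots.sort(key=lambda s: -s.peak_intensity)
    kept: list[Spot] = []
    for s in spots:
        if all(np.hypot(s.x - k.x, s.y - k.y) >= merge_radius_px for k in kept):
            kept.append(s)
    for i, s in enumerate(kept):
        s.index = i
    return kept


# --------------------------------------------------------------------------
# channel registration


def _match_mutual_nn(
    pos_a: np.ndarray, pos_b: np.ndarray, search_radius: float
) -> list[tuple[int, int]]:
    """Mutual-nearest-neighbour index pairs within a search radius."""
    if len(pos_a) == 0 or len(pos_b) == 0:
        return []
    d = cdist(pos_a, pos_b)
    nn_ab = np.argmin(d, axis=1)
    nn_ba = np.argmin(d, axis=0)
    pairs = []
    for i, j in enumerate(nn_ab):
        if nn_ba[j] == i and d[i, j] <= search_radius:
            pairs.append((i, int(j)))
    return pairs


def estimate_transform(
    bead_img_a: np.ndarray,
    bead_img_b: np.ndarray,
    model: str = "affine",
    search_radius_px: float = 15.0,
    detect_kwargs: dict | None = None,
) -> ChannelTransform:
    """Estimate the channel-A -> channel-B transform from a fiducial-bead
    image pair.

    Beads are detected in both images with Gaussian-fit refinement, matched
    by mutual nearest neighbour within ``search_radius_px``, and the
    transform fitted by least squares over matched centroids.
    """
    if model not in MIN_BEADS:
        raise InvalidParameterError(f"unknown transform model {model!r}")
    kwargs = dict(detect_frames=1, refine="gaussian")
    kwargs.update(detect_kwargs or {})
    beads_a = detect_spots(np.asarray(bead_img_a), **kwargs)
    beads_b = detect_spots(np.asarray(bead_img_b), **kwargs)
    pos_a, pos_b = as_xy_array(beads_a), as_xy_array(beads_b)
    pairs = _match_mutual_nn(pos_a, pos_b, search_radius_px)
    if len(pairs) < MIN_BEADS[model]:
        raise RegistrationError(
            f"{len(pairs)} matched beads; model {model!r} needs >= {MIN_BEADS[model]}",
            n_matched=len(pairs),
        )
    src = pos_a[[i for i, _ in pairs]]
    dst = pos_b[[j for _, j in pairs]]

    if model == "translation":
        t = (dst - src).mean(axis=0)
        matrix = np.array([[1.0, 0.0, t[0]], [0.0, 1.0, t[1]]])
    else:
        tf = sktransform.estimate_transform(
            "similarity" if model == "similarity" else "affine", src, dst
        )
        matrix = np.asarray(tf.params)[:2, :]

    mapped = src @ matrix[:, :2].T + matrix[:, 2]
    rms = float(np.sqrt(np.mean(np.sum((mapped - dst) ** 2, axis=1))))
    return ChannelTransform(matrix, residual_rms_px=rms, n_beads=len(pairs))


def fit_transform_points(
    src: np.ndarray, dst: np.ndarray, model: str = "affine"
) -> ChannelTransform:
    """Least-squares transform fit over already-matched point pairs."""
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if model not in MIN_BEADS:
        raise InvalidParameterError(f"unknown transform model {model!r}")
    if len(src) < MIN_BEADS[model] or len(src) != len(dst):
        raise RegistrationError(
            f"{len(src)} pairs; model {model!r} needs >= {MIN_BEADS[model]}",
            n_matched=len(src),
        )
    if model == "translation":
        t = (dst - src).mean(axis=0)
        matrix = np.array([[1.0, 0.0, t[0]], [0.0, 1.0, t[1]]])
    else:
        tf = sktransform.estimate_transform(
            "similarity" if model == "similarity" else "affine", src, dst
        )
        matrix = np.asarray(tf.params)[:2, :]
    mapped = src @ matrix[:, :2].T + matrix[:, 2]
    rms = float(np.sqrt(np.mean(np.sum((mapped - dst) ** 2, axis=1))))
    return ChannelTransform(matrix, residual_rms_px=rms, n_beads=len(src))


# --------------------------------------------------------------------------
# trajectory extraction


def extract_trajectory(
    stack: np.ndarray,
    spot: Spot,
    aperture_radius_px: float = 3.0,
    annulus: tuple[float, float] = (5.0, 8.0),
    frame_interval_s: float = 0.5,
) -> Trajectory:
    """Aperture photometry per frame: sum of pixels within the aperture minus
    (aperture area) x median of the background annulus.

    Raises :class:`BorderExclusionError` when the annulus does not fit inside
    the field.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise DimensionError(f"stack must be 3-D, got {stack.shape}")
    r_in, r_out = annulus
    if r_in <= aperture_radius_px or r_out <= r_in:
        raise InvalidParameterError("annulus must satisfy r_out > r_in > aperture radius")

    _, h, w = stack.shape
    if (
        spot.x - r_out < 0
        or spot.y - r_out < 0
        or spot.x + r_out > w
        or spot.y + r_out > h
    ):
        raise BorderExclusionError(
            f"spot at ({spot.x:.1f}, {spot.y:.1f}) too close to the border "
            f"for an annulus of radius {r_out}"
        )

    rad = int(np.ceil(r_out))
    c0 = int(np.floor(spot.x)) - rad
    c1 = int(np.floor(spot.x)) + rad + 1
    r0 = int(np.floor(spot.y)) - rad
    r1 = int(np.floor(spot.y)) + rad + 1
    c0, r0 = max(c0, 0), max(r0, 0)
    c1, r1 = min(c1, w), min(r1, h)
    sub = stack[:, r0:r1, c0:c1]
    ys, xs = np.mgrid[r0:r1, c0:c1]
    dist = np.hypot(xs + 0.5 - spot.x, ys + 0.5 - spot.y)
    ap_mask = dist <= aperture_radius_px
    an_mask = (dist >= r_in) & (dist <= r_out)
    if not ap_mask.any() or not an_mask.any():
        raise InvalidParameterError("empty aperture or annulus mask")

    ap_sum = sub[:, ap_mask].sum(axis=1)
    bg = np.median(sub[:, an_mask], axis=1)
    trace = ap_sum - ap_mask.sum() * bg
    return Trajectory(
        trace,
        frame_interval_s=frame_interval_s,
        channel=spot.channel,
        spot=spot,
    )
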