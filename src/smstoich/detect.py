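"""Single-emitter detection and trace extraction in TIRF image stacks.

Detection follows a square-scan procedure: candidate squares are those in
which the maximum pixel exceeds the image mean by a threshold number of
image SDs; a square is rejected if it contains more than one peak, and the
intensity profiles through the peak must conform to a Gaussian in each
dimension.  The per-channel stack is first reduced by a maximum-intensity
projection so that emitters that spend part of the record in a reversible
dark state are still detected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import curve_fit
from skimage.feature import peak_local_max

from .steps import BleachTrace

__all__ = ["ImageStack", "DetectionParams", "Spot", "EdgeSpotError",
           "max_projection", "detect_spots", "extract_trace"]


@dataclass
class ImageStack:
    """Time-ordered frames of one channel with acquisition metadata."""

    frames: np.ndarray
    exposure_ms: float = 50.0
    channel: str = "green"
    excitation_nm: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] == 0:
            raise ValueError("frames must be a non-empty (t, y, x) array")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class DetectionParams:
    """Square-scan detection parameters.

    square_size : odd side length of the scan square, pixels.
    threshold_k : candidate threshold, in image SDs above the image mean
        (image statistics are computed over the whole field).
    gaussian_fit_min_r2 : minimum R^2 of the 1-D Gaussian fits to the row
        and column profiles through the peak.
    min_sigma / max_sigma : admissible fitted PSF widths, pixels; rejects
        single-pixel noise spikes and diffuse background structure.
    smoothing_sigma : Gaussian pre-filter (pixels) applied to the working
        image used for thresholding, peak finding and the single-peak test,
        so that single-pixel noise fluctuations are not mistaken for
        peaks; profile fits and localization always use the raw image.
        Set to 0 to disable.
    """

    square_size: int = 7
    threshold_k: float = 4.0
    gaussian_fit_min_r2: float = 0.7
    min_sigma: float = 0.5
    max_sigma: float | None = None
    smoothing_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.square_size < 5 or self.square_size % 2 == 0:
            raise ValueError("square_size must be odd and >= 5")
        if self.threshold_k <= 0:
            raise ValueError("threshold_k must be positive")
        if not 0.0 <= self.gaussian_fit_min_r2 <= 1.0:
            raise ValueError("gaussian_fit_min_r2 must be in [0, 1]")


@dataclass
class Spot:
    """A detected emitter.

    Coordinates are 0-based, pixel-center convention: (x, y) = (0.0, 0.0)
    is the centre of the corner pixel.
    """

    x: float
    y: float
    channel: str = ""
    sigma_x: float = np.nan
    sigma_y: float = np.nan
    amplitude: float = np.nan
    spot_id: int | None = None

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y])


class EdgeSpotError(ValueError):
    """Spot too close to the image edge for aperture photometry."""


def max_projection(stack: ImageStack | np.ndarray) -> np.ndarray:
    """Per-pixel maximum over frames.

    Using the maximum rather than the mean guarantees that a fluorophore
    that was dark at the start (or repeatedly, given the short 1-2 s dark
    dwell relative to the 12.5 s record) still appears in the projection.
    """
    frames = stack.frames if isinstance(stack, ImageStack) else np.asarray(stack, float)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("need a non-empty (t, y, x) stack")
    return frames.max(axis=0)


def _gauss1d(x, a, c, sigma, b):
    return a * np.exp(-0.5 * ((x - c) / sigma) ** 2) + b


def _fit_profile(profile: np.ndarray, offset: float):
    """Fit a 1-D Gaussian to a profile; returns (center, sigma, amp, r2)."""
    x = np.arange(profile.size, dtype=float)
    baseline = float(profile.min())
    amp0 = float(profile.max() - baseline)
    c0 = float(np.argmax(profile))
    try:
        popt, _ = curve_fit(
            _gauss1d, x, profile,
            p0=[amp0, c0, 1.5, baseline],
            bounds=([0.0, -1.0, 0.1, -np.inf],
                    [np.inf, profile.size, profile.size, np.inf]),
            maxfev=2000)
    except RuntimeError:
        return None
    resid = profile - _gauss1d(x, *popt)
    ss_tot = float(np.sum((profile - profile.mean()) ** 2))
    if ss_tot == 0.0:
        return None
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    a, c, sigma, _ = popt
    return c + offset, float(sigma), float(a), r2


def detect_spots(image: np.ndarray, params: DetectionParams | None = None,
                 channel: str = "") -> list[Spot]:
    """Detect single emitters in a projected image.

    A candidate square passes when (i) its maximum exceeds the image mean
    by ``threshold_k`` image SDs, (ii) it contains a single peak — no
    second local maximum above half the peak height (measured above the
    image mean), and (iii) the row and column profiles through the peak
    fit a 1-D Gaussian with R^2 at or above ``gaussian_fit_min_r2`` and a
    plausible width.  Accepted spots are deduplicated so that no two
    centres lie within half a square of each other.
    """
    params = params or DetectionParams()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    if min(image.shape) <= params.square_size:
        raise ValueError("image smaller than the scan square")

    work = (gaussian_filter(image, params.smoothing_sigma)
            if params.smoothing_sigma > 0 else image)
    mean = float(work.mean())
    sd = float(work.std())
    threshold = mean + params.threshold_k * sd
    half = params.square_size // 2
    max_sigma = params.max_sigma if params.max_sigma is not None else params.square_size / 2.0

    peaks = peak_local_max(work, min_distance=1, threshold_abs=threshold,
                           exclude_border=half)
    if peaks.size:
        peaks = peaks[work[peaks[:, 0], peaks[:, 1]] > threshold]
    if peaks.size == 0:
        return []
    order = np.argsort(-work[peaks[:, 0], peaks[:, 1]])
    peaks = peaks[order]

    spots: list[Spot] = []
    for py, px in peaks:
        square = work[py - half: py + half + 1, px - half: px + half + 1]
        peak_val = work[py, px]
        # single-peak test: any other local max above half the peak (above
        # the field mean) disqualifies the square
        # min_distance=2 so that the two pixels of an exactly half-pixel-
        # centred plateau are not read as a double peak
        local = peak_local_max(square, min_distance=2,
                               threshold_abs=mean + 0.5 * (peak_val - mean))
        if len(local) > 1:
            continue
        row = _fit_profile(work[py, px - half: px + half + 1], px - half)
        col = _fit_profile(work[py - half: py + half + 1, px], py - half)
        if row is None or col is None:
            continue
        cx, sx, ax, r2x = row
        cy, sy, ay, r2y = col
        if r2x < params.gaussian_fit_min_r2 or r2y < params.gaussian_fit_min_r2:
            continue
        # widths measured on the smoothed image carry the filter width in
        # quadrature; report (and gate on) the deconvolved PSF width
        s_f = params.smoothing_sigma
        sx = math.sqrt(max(sx ** 2 - s_f ** 2, 0.0))
        sy = math.sqrt(max(sy ** 2 - s_f ** 2, 0.0))
        if not (params.min_sigma <= sx <= max_sigma
                and params.min_sigma <= sy <= max_sigma):
            continue
        if s_f > 0 and sx > 0 and sy > 0:
            # smoothing attenuates a 2-D Gaussian peak by
            # sx*sy / sqrt((sx^2+sf^2)(sy^2+sf^2)); undo it
            gain = math.sqrt((sx ** 2 + s_f ** 2) * (sy ** 2 + s_f ** 2)) / (sx * sy)
            ax *= gain
            ay *= gain
        if not (0 <= cx < image.shape[1] and 0 <= cy < image.shape[0]):
            continue
        if any((cx - s.x) ** 2 + (cy - s.y) ** 2 < (params.square_size / 2.0) ** 2
               for s in spots):
            continue
        spots.append(Spot(x=float(cx), y=float(cy), channel=channel,
                          sigma_x=sx, sigma_y=sy,
                          amplitude=float(0.5 * (ax + ay)),
                          spot_id=len(spots)))
    return spots


def _disc_offsets(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    dy, dx = np.mgrid[-r: r + 1, -r: r + 1]
    keep = dy ** 2 + dx ** 2 <= radius ** 2
    return np.stack([dy[keep], dx[keep]], axis=1)


def _annulus_offsets(r_in: float, r_out: float) -> np.ndarray:
    r = int(np.ceil(r_out))
    dy, dx = np.mgrid[-r: r + 1, -r: r + 1]
    d2 = dy ** 2 + dx ** 2
    keep = (d2 > r_in ** 2) & (d2 <= r_out ** 2)
    return np.stack([dy[keep], dx[keep]], axis=1)


def extract_trace(stack: ImageStack, spot: Spot, aperture_radius: float = 3.0,
                  annulus: tuple[float, float] = (5.0, 7.0)) -> BleachTrace:
    """Background-subtracted aperture photometry time course of one spot.

    Per frame: sum over a circular aperture around the spot centre minus
    (aperture area) x (median of an annulus) — the annulus median tracks
    the local background.

    Raises
    ------
    EdgeSpotError
        If the annulus would leave the image; callers must exclude the
        spot explicitly rather than receive a truncated trace.
    """
    frames = stack.frames
    h, w = stack.shape
    cy, cx = int(round(spot.y)), int(round(spot.x))
    margin = int(np.ceil(annulus[1]))
    if not (margin <= cy < h - margin and margin <= cx < w - margin):
        raise EdgeSpotError(
            f"spot at ({spot.x:.1f}, {spot.y:.1f}) is within {margin} px of the edge")

    ap = _disc_offsets(aperture_radius)
    ann = _annulus_offsets(*annulus)
    ap_vals = frames[:, cy + ap[:, 0], cx + ap[:, 1]]
    ann_vals = frames[:, cy + ann[:, 0], cx + ann[:, 1]]
    intensity = ap_vals.sum(axis=1) - ap.shape[0] * np.median(ann_vals, axis=1)
    return BleachTrace(intensities=intensity, exposure_ms=stack.exposure_ms,
                       spot_id=spot.spot_id, channel=stack.channel or spot.channel)
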