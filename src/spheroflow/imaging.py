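"""Quantification of spheroid time-lapse stacks.

Three readouts, mirroring a standard reporter-spheroid analysis:

* **Intensity kinetics** — ROI-integrated fluorescence density per frame,
  normalized to the first frame (I(t)/I0); the 70 h endpoint I70/I0 is the
  fold-change statistic compared across flow/ligand conditions.
* **Azimuthal profiles** — the frame is resampled onto polar coordinates
  (r, θ) about the spheroid centroid and averaged over r, giving the
  radially averaged intensity versus θ; flow imprints a top (θ=90°) vs
  bottom (θ=270°) asymmetry on this profile.
* **Motility maps** — the per-pixel temporal standard deviation of the
  bright-field channel, a proxy for local cell motion at the spheroid rim.

θ is measured counterclockwise with 90° at the image top (the inlet-facing
pole); image row indices increase downward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_fill_holes, distance_transform_edt, gaussian_filter, map_coordinates
from skimage.filters import threshold_otsu
from skimage.measure import label

__all__ = [
    "TimeLapseStack",
    "ROIMask",
    "IntensitySeries",
    "AzimuthalProfile",
    "MotilityMap",
    "segment_spheroid",
    "intensity_timeseries",
    "polar_transform",
    "azimuthal_profile",
    "aggregate_profiles",
    "asymmetry_index",
    "temporal_sd_map",
    "peripheral_motility_score",
]


@dataclass
class TimeLapseStack:
    """Multi-channel time-lapse with calibration metadata.

    channels maps a label (e.g. ``"bf"``, ``"gfp"``, ``"rfp"``) to a
    (T, H, W) float array; all channels must share the same shape.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float  # um/px
    frame_interval: float  # h

    def __post_init__(self):
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share (T, H, W)")
        (shape,) = shapes
        if len(shape) != 3:
            raise ValueError("channels must be (T, H, W) arrays")

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(f"channel {name!r} not in {sorted(self.channels)}") from None


@dataclass
class ROIMask:
    """Single-component binary region of interest around the spheroid."""

    mask: np.ndarray
    centroid: tuple[float, float] = field(init=False)  # (x, y) px
    equivalent_radius: float = field(init=False)  # px

    def __post_init__(self):
        m = np.asarray(self.mask, dtype=bool)
        if not m.any():
            raise ValueError("ROI mask is empty")
        if label(m).max() != 1:
            raise ValueError("ROI mask must be a single connected component")
        self.mask = m
        ys, xs = np.nonzero(m)
        self.centroid = (float(xs.mean()), float(ys.mean()))
        self.equivalent_radius = float(np.sqrt(m.sum() / np.pi))


@dataclass
class IntensitySeries:
    """ROI-integrated intensity per frame and its t0-normalized form."""

    times: np.ndarray  # h
    raw_density: np.ndarray  # a.u.
    normalized: np.ndarray  # I(t)/I0


@dataclass
class AzimuthalProfile:
    """Radially averaged intensity vs θ per time point, t0-normalized.

    values has shape (n_times, n_theta); theta holds bin centers in degrees.
    """

    theta: np.ndarray
    times: np.ndarray
    values: np.ndarray


@dataclass
class MotilityMap:
    """Per-pixel temporal SD image (a.u.)."""

    sd: np.ndarray


def segment_spheroid(
    frame: np.ndarray,
    method: str = "threshold",
    mask: np.ndarray | None = None,
    polarity: str = "auto",
    sigma: float = 2.0,
) -> ROIMask:
    """Segment the spheroid in a single frame, or validate a provided mask.

    Gaussian smoothing, Otsu threshold, hole filling, largest connected
    component. ``polarity`` selects bright-on-dark ("bright"), dark-on-bright
    ("dark") or the minority class ("auto" — the spheroid occupies less than
    half the field).
    """
    if method == "provided-mask":
        if mask is None:
            raise ValueError("method 'provided-mask' requires a mask")
        return ROIMask(mask=mask)
    if method != "threshold":
        raise ValueError(f"unknown segmentation method {method!r}")
    img = np.asarray(frame, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    smooth = gaussian_filter(img, sigma)
    if smooth.max() == smooth.min():
        raise ValueError("no object found: image is constant")
    thr = threshold_otsu(smooth)
    bright = smooth > thr
    if polarity == "bright":
        obj = bright
    elif polarity == "dark":
        obj = ~bright
    elif polarity == "auto":
        obj = bright if bright.mean() <= 0.5 else ~bright
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    obj = binary_fill_holes(obj)
    lab = label(obj)
    if lab.max() == 0:
        raise ValueError("no object found")
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    return ROIMask(mask=lab == largest)


def _background_annulus(roi: ROIMask, shape, inner: float = 1.3, outer: float = 1.8):
    cx, cy = roi.centroid
    r = roi.equivalent_radius
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    rad = np.hypot(xx - cx, yy - cy)
    ann = (rad >= inner * r) & (rad <= outer * r) & ~roi.mask
    return ann


def intensity_timeseries(
    stack: TimeLapseStack,
    roi: ROIMask,
    channel: str,
    background: str | None = "annulus",
    mode: str = "sum",
) -> IntensitySeries:
    """ROI intensity density per frame, normalized to t = 0.

    background="annulus" subtracts the per-frame median of a background
    annulus outside the ROI from every pixel; None disables subtraction.
    mode="sum" integrates over the ROI (integrated density); "mean" averages.
    """
    frames = stack.channel(channel)
    if roi.mask.shape != frames.shape[1:]:
        raise ValueError("ROI shape does not match frames")
    vals = frames[:, roi.mask].astype(float)
    if background == "annulus":
        ann = _background_annulus(roi, frames.shape[1:])
        if ann.any():
            bg = np.median(frames[:, ann], axis=1)
            vals = vals - bg[:, None]
        else:
            warnings.warn("background annulus empty; skipping subtraction")
    elif background is not None:
        raise ValueError(f"unknown background mode {background!r}")
    raw = vals.sum(axis=1) if mode == "sum" else vals.mean(axis=1)
    if mode not in ("sum", "mean"):
        raise ValueError(f"unknown mode {mode!r}")
    if raw[0] == 0:
        raise ValueError("zero intensity at t = 0: normalization undefined")
    return IntensitySeries(
        times=stack.times, raw_density=raw, normalized=raw / raw[0]
    )


def polar_transform(
    image: np.ndarray,
    center: tuple[float, float],
    r_max: float,
    n_r: int | None = None,
    n_theta: int = 360,
) -> np.ndarray:
    """Resample an image onto an (r, θ) lattice about ``center``.

    Returns a (n_r, n_theta) array; row ir corresponds to radius
    (ir + 0.5) * r_max / n_r, column it to θ = (it + 0.5) * 360 / n_theta,
    counterclockwise with 90° at the image top. Bilinear interpolation;
    samples outside the frame are clipped to the edge with a warning.
    """
    img = np.asarray(image, dtype=float)
    cx, cy = center
    if not (0 <= cx < img.shape[1] and 0 <= cy < img.shape[0]):
        raise ValueError("center outside image")
    if r_max <= 0:
        raise ValueError("r_max must be positive")
    bound = min(cx, cy, img.shape[1] - 1 - cx, img.shape[0] - 1 - cy)
    if r_max > bound:
        warnings.warn(f"r_max {r_max:.1f} px exceeds image bounds; clipping to {bound:.1f}")
        r_max = bound
    if n_r is None:
        n_r = max(1, int(round(r_max)))
    rs = (np.arange(n_r) + 0.5) * r_max / n_r
    th = np.deg2rad((np.arange(n_theta) + 0.5) * 360.0 / n_theta)
    rr, tt = np.meshgrid(rs, th, indexing="ij")
    xs = cx + rr * np.cos(tt)
    ys = cy - rr * np.sin(tt)
    return map_coordinates(img, [ys, xs], order=1, mode="nearest")


def azimuthal_profile(
    stack: TimeLapseStack,
    roi: ROIMask,
    channel: str,
    times: np.ndarray | list | None = None,
    r_max: float | None = None,
    n_theta: int = 360,
    background: str | None = "annulus",
) -> AzimuthalProfile:
    """Radially averaged intensity vs θ per requested time, t0-normalized.

    Each frame is polar-transformed about the ROI centroid and averaged over
    r in (0, r_max] per θ bin. All profiles are divided by the mean of the
    t = 0 profile of the same spheroid, so the initial profile has mean 1.
    """
    frames = stack.channel(channel)
    if r_max is None:
        r_max = roi.equivalent_radius
    if r_max <= 0:
        raise ValueError("empty radial range")
    all_times = stack.times
    if times is None:
        sel = np.arange(stack.n_frames)
    else:
        sel = []
        for t in np.atleast_1d(times):
            k = np.flatnonzero(np.isclose(all_times, t))
            if k.size == 0:
                raise ValueError(f"time {t} h not present in stack")
            sel.append(k[0])
        sel = np.asarray(sel)
    if 0 not in sel:
        sel = np.concatenate([[0], sel])  # t0 needed for normalization

    bg = None
    if background == "annulus":
        ann = _background_annulus(roi, frames.shape[1:])
        if ann.any():
            bg = np.median(frames[:, ann], axis=1)

    profs = {}
    for k in sel:
        img = frames[k].astype(float)
        if bg is not None:
            img = img - bg[k]
        pol = polar_transform(img, roi.centroid, r_max, n_theta=n_theta)
        profs[k] = pol.mean(axis=0)
    norm = profs[0].mean()
    if norm == 0:
        raise ValueError("zero t = 0 profile: normalization undefined")
    keep = np.asarray(sorted(set(sel.tolist())))
    theta = (np.arange(n_theta) + 0.5) * 360.0 / n_theta
    values = np.vstack([profs[k] / norm for k in keep])
    return AzimuthalProfile(theta=theta, times=all_times[keep], values=values)


def aggregate_profiles(profiles: list[AzimuthalProfile]) -> tuple[AzimuthalProfile, np.ndarray]:
    """Mean ± SD across spheroids; returns (mean profile, SD array)."""
    if not profiles:
        raise ValueError("no profiles to aggregate")
    ref = profiles[0]
    for p in profiles[1:]:
        if p.values.shape != ref.values.shape:
            raise ValueError("profiles have mismatched shapes")
    stackv = np.stack([p.values for p in profiles])
    mean = AzimuthalProfile(theta=ref.theta, times=ref.times, values=stackv.mean(axis=0))
    return mean, stackv.std(axis=0)


def asymmetry_index(profile: AzimuthalProfile, t: float) -> tuple[float, float, float]:
    """(top, bottom, top/bottom) profile values at θ = 90° and 270° at time t."""
    k = np.flatnonzero(np.isclose(profile.times, t))
    if k.size == 0:
        raise ValueError(f"time {t} h not present in profile")
    row = profile.values[k[0]]
    top = float(row[np.argmin(np.abs(profile.theta - 90.0))])
    bottom = float(row[np.argmin(np.abs(profile.theta - 270.0))])
    return top, bottom, top / bottom


def temporal_sd_map(
    stack: TimeLapseStack,
    channel: str = "bf",
    ddof: int = 0,
    register: bool = False,
) -> MotilityMap:
    """Per-pixel temporal standard deviation across frames.

    Population SD (ddof=0) by default. Optional rigid registration by
    phase correlation against the first frame compensates stage drift.
    """
    frames = stack.channel(channel).astype(float)
    if frames.shape[0] < 2:
        raise ValueError("temporal SD requires at least 2 frames")
    if register:
        from scipy.ndimage import shift as nd_shift
        from skimage.registration import phase_cross_correlation

        ref = frames[0]
        reg = [ref]
        for f in frames[1:]:
            dy_dx, _, _ = phase_cross_correlation(ref, f, upsample_factor=10)
            reg.append(nd_shift(f, dy_dx, order=1, mode="nearest"))
        frames = np.stack(reg)
    return MotilityMap(sd=frames.std(axis=0, ddof=ddof))


def peripheral_motility_score(
    mot: MotilityMap,
    roi: ROIMask,
    band_width: float,
    pixel_size: float = 1.0,
) -> float:
    """Mean temporal SD in a peripheral annulus relative to far background.

    The annulus extends band_width (um) outward from the ROI boundary; the
    background region is everything farther than 2x band_width beyond it.
    """
    band_px = band_width / pixel_size
    if band_px <= 0:
        raise ValueError("band width must be positive")
    dist = distance_transform_edt(~roi.mask)
    annulus = (dist > 0) & (dist <= band_px)
    background = dist > 3.0 * band_px
    if not annulus.any():
        raise ValueError("empty peripheral annulus")
    if not background.any():
        raise ValueError("no background region beyond the annulus")
    num = float(mot.sd[annulus].mean())
    den = float(mot.sd[background].mean())
    if den == 0.0:
        if num == 0.0:
            warnings.warn("all-zero motility map; score defined as 0")
            return 0.0
        warnings.warn("zero background SD; score is infinite")
        return float("inf")
    return num / den
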