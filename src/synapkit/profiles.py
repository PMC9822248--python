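"""Side-view synapse quantification from multi-channel STED/confocal images.

Workflow: the elongated PSD signal is fit with an ellipse (image moments) to
get its center and orientation; a ~1200-nm-long, 200-nm-wide rectangle is
placed perpendicular to and across the center of the PSD band; per-channel
intensity profiles along that rectangle (averaged over its width) are
aligned to the peak of the 5-pixel moving-average-smoothed PSD signal and
reported from -400 nm (presynaptic) to +200 nm (postsynaptic).  Per-profile
peak values are taken independent of peak position.  All analysis runs on
raw intensities without background subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import AmbiguousOrientationError, GeometryError, InputError

__all__ = [
    "SideViewROI", "RawProfile", "LineProfileSet",
    "fit_psd_ellipse", "extract_profile", "align_profiles", "profile_peak",
    "channel_peak_positions",
]

#: Channel order convention: (vesicle marker, PSD, test protein).
VESICLE_CHANNEL, PSD_CHANNEL, TEST_CHANNEL = 0, 1, 2


@dataclass(frozen=True)
class SideViewROI:
    """Ellipse fit of a PSD mask: center, orientation and axis ratio."""

    center_px: tuple[float, float]   # (x, y)
    orientation_deg: float           # major axis, CCW from x, in [0, 180)
    axis_ratio: float                # major / minor
    pixel_size: float                # nm / pixel


@dataclass(frozen=True)
class RawProfile:
    """Unaligned per-channel intensities along the extraction rectangle."""

    axis_nm: np.ndarray        # signed, negative = presynaptic, 0 = ellipse center
    intensities: np.ndarray    # (n_channels, n_positions)
    roi: SideViewROI


@dataclass(frozen=True)
class LineProfileSet:
    """Aligned profiles of many synapses on a common nm axis.

    The PSD channel is stored smoothed (it is the alignment reference); the
    other channels are raw.  ``peak_values[s, c]`` is the maximum of profile
    ``s`` in channel ``c`` over the reported axis, independent of position.
    """

    axis_nm: np.ndarray          # strictly increasing, 0 at the PSD peak
    profiles: np.ndarray         # (n_synapses, n_channels, n_positions), NaN outside data
    peak_values: np.ndarray      # (n_synapses, n_channels)
    edge_flags: np.ndarray       # (n_synapses,) True if the PSD peak hit the window edge
    smoothing: int
    aligned: bool = True

    @property
    def mean_profiles(self) -> np.ndarray:
        """Per-position mean across synapses (NaN-aware), (n_channels, n_positions)."""
        return np.nanmean(self.profiles, axis=0)

    @property
    def sem_profiles(self) -> np.ndarray:
        n = np.sum(~np.isnan(self.profiles), axis=0)
        return np.nanstd(self.profiles, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))


# --------------------------------------------------------------------------
# ellipse fit
# --------------------------------------------------------------------------
def fit_psd_ellipse(mask: np.ndarray, intensity: np.ndarray | None = None, *,
                    pixel_size: float = 11.4,
                    min_axis_ratio: float = 1.3) -> SideViewROI:
    """Fit the PSD mask with an ellipse from (intensity-weighted) image moments.

    The center is the weighted centroid and the orientation the major-axis
    angle of the second-moment ellipse.  A mask too close to circular
    (major/minor below ``min_axis_ratio``) has no defined orientation and
    raises :class:`AmbiguousOrientationError`.
    """
    mask = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise InputError("empty PSD mask")
    w = np.ones(ys.size) if intensity is None else np.asarray(intensity, float)[ys, xs]
    if np.any(w < 0) or w.sum() <= 0:
        raise InputError("intensity weights must be non-negative with positive sum")
    wsum = w.sum()
    cx = float((w * xs).sum() / wsum)
    cy = float((w * ys).sum() / wsum)
    dx, dy = xs - cx, ys - cy
    mxx = (w * dx * dx).sum() / wsum
    myy = (w * dy * dy).sum() / wsum
    mxy = (w * dx * dy).sum() / wsum
    cov = np.array([[mxx, mxy], [mxy, myy]])
    evals, evecs = np.linalg.eigh(cov)           # ascending
    minor, major = evals
    if minor <= 0:
        ratio = np.inf
    else:
        ratio = float(np.sqrt(major / minor))
    if ratio < min_axis_ratio:
        raise AmbiguousOrientationError(
            f"mask is near-circular (axis ratio {ratio:.2f} < {min_axis_ratio})"
        )
    vx, vy = evecs[:, 1]
    angle = np.degrees(np.arctan2(vy, vx)) % 180.0
    return SideViewROI(center_px=(cx, cy), orientation_deg=float(angle),
                       axis_ratio=ratio, pixel_size=pixel_size)


# --------------------------------------------------------------------------
# profile extraction
# --------------------------------------------------------------------------
def extract_profile(image: np.ndarray, roi: SideViewROI, *,
                    length_nm: float = 1200.0, width_nm: float = 200.0,
                    vesicle_channel: int = VESICLE_CHANNEL) -> RawProfile:
    """Per-channel intensity profile across the synapse.

    The rectangle's long axis is perpendicular to the PSD ellipse's major
    axis and passes through its center; intensities are bilinearly sampled
    at pixel-pitch steps and averaged over the 200 nm width.  The negative
    (presynaptic) end of the axis is assigned toward the vesicle-channel
    centroid.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3:
        raise InputError("image must be (n_channels, H, W)")
    n_ch, h, w = image.shape
    step = roi.pixel_size
    th = np.deg2rad(roi.orientation_deg)
    major = np.array([np.cos(th), np.sin(th)])      # along the PSD band (x, y)
    axis = np.array([-np.sin(th), np.cos(th)])      # across the synapse (x, y)

    k = int(np.floor((length_nm / 2) / step))
    j = int(np.floor((width_nm / 2) / step))
    a_nm = np.arange(-k, k + 1) * step
    w_nm = np.arange(-j, j + 1) * step

    cx, cy = roi.center_px
    # sample grid: (n_positions, n_width) points in pixel coordinates
    px = cx + (a_nm[:, None] * axis[0] + w_nm[None, :] * major[0]) / step
    py = cy + (a_nm[:, None] * axis[1] + w_nm[None, :] * major[1]) / step
    if px.min() < 0 or py.min() < 0 or px.max() > w - 1 or py.max() > h - 1:
        raise GeometryError("extraction rectangle exits the image")

    profiles = np.empty((n_ch, a_nm.size))
    for c in range(n_ch):
        vals = map_coordinates(image[c], [py.ravel(), px.ravel()], order=1)
        profiles[c] = vals.reshape(py.shape).mean(axis=1)

    # orient the axis: presynaptic (negative) side toward the vesicle cloud
    ves = image[vesicle_channel]
    tot = ves.sum()
    if tot > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        vcx = (ves * xx).sum() / tot
        vcy = (ves * yy).sum() / tot
        if (vcx - cx) * axis[0] + (vcy - cy) * axis[1] > 0:
            a_nm = -a_nm[::-1]
            profiles = profiles[:, ::-1]
    return RawProfile(axis_nm=a_nm, intensities=profiles, roi=roi)


# --------------------------------------------------------------------------
# alignment and peaks
# --------------------------------------------------------------------------
def moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with a shrinking window at the edges."""
    if window < 1 or window % 2 == 0:
        raise InputError("smoothing window must be a positive odd integer")
    kernel = np.ones(window)
    sums = np.convolve(y, kernel, mode="same")
    counts = np.convolve(np.ones_like(y), kernel, mode="same")
    return sums / counts


def _peak_index(y: np.ndarray, axis_nm: np.ndarray) -> int:
    """Index of the maximum; ties broken toward the position closest to 0 nm."""
    m = y.max()
    candidates = np.nonzero(y == m)[0]
    return int(candidates[np.argmin(np.abs(axis_nm[candidates]))])


def align_profiles(raw: list[RawProfile], *, psd_channel: int = PSD_CHANNEL,
                   smoothing: int = 5,
                   report_range: tuple[float, float] = (-400.0, 200.0)) -> LineProfileSet:
    """Align raw profiles to the smoothed PSD peak and crop to the report range.

    The PSD channel is smoothed with a centered moving average of
    ``smoothing`` samples; the peak of the smoothed signal defines position
    0 nm and all channels (vesicle, test protein, smoothed PSD) shift with
    it.  Profiles are then interpolated onto a common axis restricted to
    ``report_range`` (default -400 nm presynaptic to +200 nm postsynaptic);
    positions without data are NaN.  Peak values per profile and channel are
    the maxima over the reported axis regardless of position.
    """
    if not raw:
        raise InputError("no profiles to align")
    step = float(raw[0].axis_nm[1] - raw[0].axis_nm[0])
    lo, hi = report_range
    common = np.arange(np.ceil(lo / step), np.floor(hi / step) + 1) * step

    n_ch = raw[0].intensities.shape[0]
    out = np.full((len(raw), n_ch, common.size), np.nan)
    edge = np.zeros(len(raw), dtype=bool)
    for s, rp in enumerate(raw):
        smoothed = moving_average(rp.intensities[psd_channel], smoothing)
        pk = _peak_index(smoothed, rp.axis_nm)
        edge[s] = pk in (0, rp.axis_nm.size - 1)
        shifted_axis = rp.axis_nm - rp.axis_nm[pk]
        channels = rp.intensities.copy()
        channels[psd_channel] = smoothed
        for c in range(n_ch):
            out[s, c] = _regrid(shifted_axis, channels[c], common)
    peaks = np.nanmax(out, axis=2)
    return LineProfileSet(axis_nm=common, profiles=out, peak_values=peaks,
                          edge_flags=edge, smoothing=smoothing)


def _regrid(x: np.ndarray, y: np.ndarray, grid: np.ndarray) -> np.ndarray:
    out = np.interp(grid, x, y, left=np.nan, right=np.nan)
    return out


def profile_peak(profile: np.ndarray) -> float:
    """Maximum intensity of a profile, independent of where it occurs."""
    profile = np.asarray(profile, dtype=float)
    if profile.size == 0:
        raise InputError("empty profile")
    return float(np.nanmax(profile))


def channel_peak_positions(profiles: LineProfileSet, channel: int) -> np.ndarray:
    """Per-synapse axis position (nm) of the channel's maximum."""
    pos = np.empty(profiles.profiles.shape[0])
    for s in range(pos.size):
        y = profiles.profiles[s, channel]
        valid = ~np.isnan(y)
        idx = np.nonzero(valid)[0]
        sub = y[idx]
        pos[s] = profiles.axis_nm[idx[_peak_index(sub, profiles.axis_nm[idx])]]
    return pos
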