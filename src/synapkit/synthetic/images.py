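"""Synthetic STED/confocal synapse images and puncta fields.

Side-view synapses are rendered as three channels in fixed order
(vesicle marker, PSD scaffold, test protein):

* the PSD is an anisotropic Gaussian ridge (elongated band) of given
  length, width and orientation;
* the vesicle cloud is an isotropic Gaussian centered on the presynaptic
  side of the PSD;
* the test protein is a band parallel to the PSD whose center sits at a
  signed trans-synaptic offset (negative = presynaptic), the quantity the
  line-profile analysis recovers.

Noise is additive Gaussian (detector-like).  The default pixel size of
11.4 nm matches 4096 x 4096 scanning of a 46.51 x 46.51 um field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ParameterError, PlacementError

__all__ = [
    "SynapseImageParams", "SideViewGroundTruth", "simulate_sideview_image",
    "ground_truth_psd_mask", "PunctaFieldParams", "PunctaGroundTruth",
    "simulate_puncta_field",
]

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # sigma -> FWHM factor


# --------------------------------------------------------------------------
# side-view synapses
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class SynapseImageParams:
    """Geometry and intensities of one rendered side-view synapse.

    Lengths are in nm; ``psd_orientation`` is the angle of the PSD long
    axis in degrees CCW from the image x (column) axis; ``psd_center`` is
    in pixels (defaults to the image center).  ``test_peak_offset`` is the
    signed trans-synaptic position of the test-protein band (negative =
    presynaptic).  ``channel_amplitudes`` are (vesicle, PSD, test protein).
    """

    pixel_size: float = 11.4                       # nm / pixel
    image_size: tuple[int, int] = (256, 256)       # rows, cols
    psd_length: float = 350.0                      # nm, FWHM of the band
    psd_width: float = 80.0                        # nm, FWHM across the band
    psd_orientation: float = 0.0                   # degrees
    psd_center: tuple[float, float] | None = None  # (x, y) pixels
    vesicle_cloud_sigma: float = 150.0             # nm
    vesicle_offset: float = 180.0                  # nm, presynaptic distance
    test_peak_offset: float = -45.0                # nm, signed
    test_width: float = 60.0                       # nm, FWHM of the test band
    channel_amplitudes: tuple[float, float, float] = (150.0, 200.0, 180.0)
    background_level: float = 10.0                 # a.u.
    noise_sd: float = 5.0                          # a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if min(self.image_size) < 8:
            raise ParameterError("image too small")
        cx, cy = self.center_px
        half = self.psd_length / 2.0 / self.pixel_size
        h, w = self.image_size
        if not (half <= cx <= w - 1 - half and half <= cy <= h - 1 - half):
            raise ParameterError("PSD does not fit inside the image")

    @property
    def center_px(self) -> tuple[float, float]:
        if self.psd_center is not None:
            return self.psd_center
        h, w = self.image_size
        return ((w - 1) / 2.0, (h - 1) / 2.0)


@dataclass(frozen=True)
class SideViewGroundTruth:
    """True geometry of a rendered side-view synapse."""

    center_px: tuple[float, float]
    orientation_deg: float
    test_peak_offset: float     # nm, signed (negative = presynaptic)
    vesicle_offset: float       # nm
    channel_amplitudes: tuple[float, float, float]


def _synapse_fields(params: SynapseImageParams) -> tuple[np.ndarray, np.ndarray]:
    """(u, a): nm coordinates along the PSD axis and across the synapse.

    ``a`` is the trans-synaptic axis coordinate, positive postsynaptic;
    the vesicle cloud sits at negative ``a``.
    """
    h, w = params.image_size
    cx, cy = params.center_px
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dx = (xx - cx) * params.pixel_size
    dy = (yy - cy) * params.pixel_size
    th = np.deg2rad(params.psd_orientation)
    u = np.cos(th) * dx + np.sin(th) * dy          # along the PSD band
    a = -np.sin(th) * dx + np.cos(th) * dy         # across the synapse
    return u, a


def simulate_sideview_image(
    params: SynapseImageParams,
) -> tuple[np.ndarray, SideViewGroundTruth]:
    """Render a (3, H, W) side-view synapse image plus ground truth.

    Channel order: vesicle marker, PSD, test protein.  Deterministic under
    a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    u, a = _synapse_fields(params)
    s_len = params.psd_length / _FWHM
    s_wid = params.psd_width / _FWHM
    s_test = params.test_width / _FWHM
    amp_v, amp_p, amp_t = params.channel_amplitudes

    along = np.exp(-(u**2) / (2 * s_len**2))
    psd = amp_p * along * np.exp(-(a**2) / (2 * s_wid**2))
    test = amp_t * along * np.exp(-((a - params.test_peak_offset) ** 2) / (2 * s_test**2))
    sv = params.vesicle_cloud_sigma
    vesicle = amp_v * np.exp(-((u**2) + (a + params.vesicle_offset) ** 2) / (2 * sv**2))

    img = np.stack([vesicle, psd, test]) + params.background_level
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    truth = SideViewGroundTruth(
        center_px=params.center_px,
        orientation_deg=params.psd_orientation % 180.0,
        test_peak_offset=params.test_peak_offset,
        vesicle_offset=params.vesicle_offset,
        channel_amplitudes=params.channel_amplitudes,
    )
    return img, truth


def ground_truth_psd_mask(params: SynapseImageParams,
                          level: float = 0.5) -> np.ndarray:
    """Boolean PSD mask from the noise-free PSD channel at `level` x max.

    Stands in for the manually drawn ROI around the PSD signal.
    """
    u, a = _synapse_fields(params)
    s_len = params.psd_length / _FWHM
    s_wid = params.psd_width / _FWHM
    psd = np.exp(-(u**2) / (2 * s_len**2) - (a**2) / (2 * s_wid**2))
    return psd >= level


# --------------------------------------------------------------------------
# puncta fields
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class PunctaFieldParams:
    """A random field of round fluorescent puncta.

    ``radius_range`` (nm) is the apparent punctum radius; spots are
    rendered as isotropic Gaussians with sigma = radius / 2.  Centers are
    rejection-sampled to keep a minimum pairwise separation.
    """

    n_puncta: int = 50
    radius_range: tuple[float, float] = (60.0, 120.0)   # nm
    intensity_range: tuple[float, float] = (100.0, 200.0)  # a.u., peak above bg
    background_level: float = 10.0
    noise_sd: float = 5.0
    min_separation: float = 500.0                       # nm, center-to-center
    image_size: tuple[int, int] = (512, 512)
    pixel_size: float = 11.4                            # nm / pixel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_puncta < 0 or self.min_separation < 0:
            raise ParameterError("n_puncta and min_separation must be >= 0")
        if self.pixel_size <= 0 or self.noise_sd < 0:
            raise ParameterError("pixel_size > 0 and noise_sd >= 0 required")
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise ParameterError("invalid radius_range")


@dataclass(frozen=True)
class PunctaGroundTruth:
    """True centers (pixels), radii (nm) and peak intensities of a field."""

    centers_px: np.ndarray     # (n, 2) as (x, y)
    radii_nm: np.ndarray
    intensities: np.ndarray


def simulate_puncta_field(
    params: PunctaFieldParams,
) -> tuple[np.ndarray, PunctaGroundTruth]:
    """Render a (H, W) puncta field plus the ground-truth object list."""
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    margin = 2.0 * params.radius_range[1] / params.pixel_size
    min_sep_px = params.min_separation / params.pixel_size

    centers: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 10_000 * max(1, params.n_puncta)
    while len(centers) < params.n_puncta:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {params.n_puncta} puncta at separation "
                f"{params.min_separation} nm in a {h}x{w} image"
            )
        attempts += 1
        x = rng.uniform(margin, w - 1 - margin)
        y = rng.uniform(margin, h - 1 - margin)
        if all((x - cx) ** 2 + (y - cy) ** 2 >= min_sep_px**2 for cx, cy in centers):
            centers.append((x, y))

    radii = rng.uniform(*params.radius_range, size=params.n_puncta)
    intens = rng.uniform(*params.intensity_range, size=params.n_puncta)

    img = np.full((h, w), float(params.background_level))
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    for (x, y), r, a in zip(centers, radii, intens):
        sigma_px = (r / 2.0) / params.pixel_size
        d2 = (xx - x) ** 2 + (yy - y) ** 2
        img += a * np.exp(-d2 / (2 * sigma_px**2))
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    truth = PunctaGroundTruth(
        centers_px=np.array(centers, dtype=float).reshape(-1, 2),
        radii_nm=radii, intensities=intens,
    )
    return img, truth
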