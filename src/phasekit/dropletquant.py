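"""Droplet quantification in two-channel fluorescence images.

Covers three measurements made on condensate droplets sedimented onto a
coverslip:

* **Dye quantum-yield corrections.**  Fluorophore quantum yields rise in the
  viscous dense phase, so raw intensity ratios overstate (or understate)
  partitioning.  :func:`dye_correction_from_spectra` integrates emission
  spectra recorded in water/glycerol mixtures over the microscope bandpass,
  normalizes to the water value, and averages the plateau above a viscosity
  floor; the published constants for the two dyes used in the source assays
  (AlexaFluor 488: 0.73, AlexaFluor 647: 1.43) ship as presets.

* **Partition coefficients.**  Droplets are segmented by a global Otsu
  threshold on the designated mask channel, connected components with
  equivalent diameter above 2 µm are retained, and the partition coefficient
  per channel is PC = [(I_DP - I_bkrd)/c_corr] / (I_LP - I_bkrd), with I_DP
  the mean intensity under the mask, I_LP the mean inside a 5-µm-diameter
  circle placed in the light phase away from all droplets, and I_bkrd the
  mean of a central ROI on a buffer-only image.

* **FRAP.**  Recovery traces normalized to the pre-bleach mean are fit with a
  single exponential with an immobile fraction,
  I(t) = I0 + A·(1 - exp(-t/τ)), giving mobile fraction (I0 + A - I_bleach) /
  (1 - I_bleach) and half-time τ·ln2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage, optimize
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops

__all__ = [
    "FluorescenceImage",
    "DyeCorrection",
    "DYE_CORRECTIONS",
    "SegmentationResult",
    "PartitionResult",
    "FrapTrace",
    "FrapFit",
    "dye_correction_from_spectra",
    "segment_droplets",
    "place_light_phase_roi",
    "partition_coefficient",
    "fit_frap",
    "read_tiff",
]


@dataclass(frozen=True)
class FluorescenceImage:
    """A single-channel 2-D fluorescence image with physical pixel size."""

    data: np.ndarray = field(repr=False)  # 2-D, intensities >= 0
    pixel_size_um: float  # µm per pixel
    channel: str = "other"  # e.g. "AF488", "AF647"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2:
            raise ValueError("image must be 2-D")
        if np.any(arr < 0):
            raise ValueError("image intensities must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")
        object.__setattr__(self, "data", arr)


@dataclass(frozen=True)
class DyeCorrection:
    """Quantum-yield correction factor for one dye over a bandpass window."""

    dye: str
    bandpass_nm: tuple[float, float]
    c_corr: float

    def __post_init__(self) -> None:
        if self.c_corr <= 0:
            raise ValueError("c_corr must be > 0")


#: Published correction factors for the two imaging dyes, defined over the
#: microscope bandpass windows they were integrated on.
DYE_CORRECTIONS: dict[str, DyeCorrection] = {
    "AF488": DyeCorrection(dye="AF488", bandpass_nm=(500.0, 550.0), c_corr=0.73),
    "AF647": DyeCorrection(dye="AF647", bandpass_nm=(650.0, 800.0), c_corr=1.43),
}


def dye_correction_from_spectra(
    wavelengths_nm: np.ndarray,
    spectra: Sequence[np.ndarray],
    viscosities_pa_s: Sequence[float],
    bandpass_nm: tuple[float, float],
    dye: str = "dye",
    viscosity_floor: float = 0.3,
    water_viscosity: float = 1.0e-3,
) -> DyeCorrection:
    """Average relative integrated-emission change at viscosities above a floor.

    Each spectrum is integrated over ``bandpass_nm`` (trapezoid rule) and
    normalized to the spectrum whose viscosity is closest to that of water;
    the correction factor is the mean of the normalized values measured at
    viscosity > ``viscosity_floor`` (Pa·s), where the quantum-yield change
    plateaus.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    visc = np.asarray(viscosities_pa_s, dtype=float)
    if len(spectra) != len(visc):
        raise ValueError("one viscosity per spectrum required")
    lo, hi = bandpass_nm
    sel = (wl >= lo) & (wl <= hi)
    if sel.sum() < 2:
        raise ValueError("bandpass window covers fewer than 2 wavelength samples")
    integrals = np.array([np.trapezoid(np.asarray(s, float)[sel], wl[sel]) for s in spectra])
    i_water = int(np.argmin(np.abs(visc - water_viscosity)))
    if visc[i_water] > 10 * water_viscosity:
        raise ValueError("no water-like reference spectrum (η ≈ 0.001 Pa·s) provided")
    plateau = integrals[visc > viscosity_floor]
    if plateau.size == 0:
        raise ValueError(f"no spectrum with viscosity above floor {viscosity_floor} Pa·s")
    c_corr = float(np.mean(plateau) / integrals[i_water])
    return DyeCorrection(dye=dye, bandpass_nm=bandpass_nm, c_corr=c_corr)


@dataclass
class SegmentationResult:
    """Labelled droplet mask plus per-object geometry and intensities."""

    labels: np.ndarray = field(repr=False)  # int label image, 0 = background
    pixel_size_um: float
    threshold: float
    diameters_um: np.ndarray = field(repr=False)  # equivalent diameter per object
    mean_intensities: np.ndarray = field(repr=False)  # on the mask channel

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0


def segment_droplets(
    image: FluorescenceImage,
    min_diameter_um: float = 2.0,
) -> SegmentationResult:
    """Otsu-threshold the image and keep 8-connected objects larger than 2 µm.

    The equivalent diameter of an object of ``area`` pixels is
    ``2*sqrt(area/pi)*pixel_size``; objects must exceed ``min_diameter_um``
    (strictly) to be retained.  Labels are renumbered contiguously from 1.
    Raises on a constant image, for which no threshold exists.
    """
    data = image.data
    if np.ptp(data) == 0:
        raise ValueError("no threshold: image is constant")
    thresh = float(threshold_otsu(data))
    binary = data > thresh
    labels = sk_label(binary, connectivity=2)  # 8-connected
    out = np.zeros_like(labels)
    diams, means = [], []
    next_label = 1
    for prop in regionprops(labels, intensity_image=data):
        diam = 2.0 * np.sqrt(prop.area / np.pi) * image.pixel_size_um
        if diam > min_diameter_um:
            out[labels == prop.label] = next_label
            diams.append(diam)
            means.append(float(prop.intensity_mean))
            next_label += 1
    return SegmentationResult(
        labels=out,
        pixel_size_um=image.pixel_size_um,
        threshold=thresh,
        diameters_um=np.array(diams),
        mean_intensities=np.array(means),
    )


def place_light_phase_roi(
    segmentation: SegmentationResult,
    roi_diameter_um: float = 5.0,
) -> np.ndarray:
    """Boolean mask of a circular light-phase ROI placed away from all droplets.

    The circle center is the pixel maximizing the Euclidean distance to the
    nearest droplet pixel (ties broken by raster order), mirroring the manual
    practice of placing the ROI "in the background, away from any fluorescent
    objects".  Raises if the most distant pixel cannot fit the full circle
    without touching a droplet.
    """
    px = segmentation.pixel_size_um
    radius_px = roi_diameter_um / 2.0 / px
    dist = ndimage.distance_transform_edt(~segmentation.mask)
    center = np.unravel_index(int(np.argmax(dist)), dist.shape)
    if dist[center] <= radius_px:
        raise ValueError("no droplet-free region large enough for the light-phase ROI")
    yy, xx = np.indices(segmentation.labels.shape)
    roi = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px**2
    return roi


@dataclass(frozen=True)
class PartitionResult:
    """Background-subtracted, dye-corrected partition coefficient for one channel."""

    channel: str
    i_dp: float
    i_lp: float
    i_bkrd: float
    c_corr: float
    pc: float
    n_objects: int


def partition_coefficient(
    channel_image: FluorescenceImage,
    segmentation: SegmentationResult,
    background_image: FluorescenceImage,
    correction: DyeCorrection,
    light_phase_roi: np.ndarray | None = None,
    background_roi_diameter_um: float = 5.0,
) -> PartitionResult:
    """PC = [(I_DP - I_bkrd)/c_corr] / (I_LP - I_bkrd) for one channel.

    The segmentation mask (computed on the designated mask channel) is applied
    unchanged to ``channel_image``.  ``light_phase_roi`` defaults to the
    automatic placement of :func:`place_light_phase_roi`; I_bkrd is the mean
    of a central circular ROI on the buffer-only image.
    """
    if channel_image.data.shape != segmentation.labels.shape:
        raise ValueError("channel image and segmentation shapes differ")
    if segmentation.n_objects == 0:
        raise ValueError("segmentation contains no droplets")
    if light_phase_roi is None:
        light_phase_roi = place_light_phase_roi(segmentation)
    elif light_phase_roi[segmentation.mask].any():
        raise ValueError("light-phase ROI intersects a segmented droplet")

    i_dp = float(channel_image.data[segmentation.mask].mean())
    i_lp = float(channel_image.data[light_phase_roi].mean())

    bg = background_image.data
    cy, cx = (s / 2.0 for s in bg.shape)
    r_px = background_roi_diameter_um / 2.0 / background_image.pixel_size_um
    yy, xx = np.indices(bg.shape)
    central = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
    i_bkrd = float(bg[central].mean())

    if i_lp <= i_bkrd:
        raise ValueError("light phase indistinguishable from background")
    pc = ((i_dp - i_bkrd) / correction.c_corr) / (i_lp - i_bkrd)
    return PartitionResult(
        channel=channel_image.channel,
        i_dp=i_dp,
        i_lp=i_lp,
        i_bkrd=i_bkrd,
        c_corr=correction.c_corr,
        pc=pc,
        n_objects=segmentation.n_objects,
    )


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrapTrace:
    """A FRAP time course with the index of the first post-bleach frame."""

    time_s: np.ndarray = field(repr=False)
    intensity: np.ndarray = field(repr=False)
    bleach_index: int

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, float)
        y = np.asarray(self.intensity, float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("time and intensity must be 1-D arrays of equal length")
        if not (0 < self.bleach_index < len(t)):
            raise ValueError("bleach index must be inside the trace")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "intensity", y)


@dataclass(frozen=True)
class FrapFit:
    """Single-exponential FRAP fit: I(t) = I0 + A·(1 - exp(-t/τ)) post-bleach."""

    converged: bool
    mobile_fraction: float | None = None
    half_time_s: float | None = None
    tau_s: float | None = None
    i_bleach: float | None = None
    plateau: float | None = None
    residual_rms: float | None = None


def fit_frap(trace: FrapTrace) -> FrapFit:
    """Fit a single-exponential recovery with immobile fraction.

    The trace is normalized to its pre-bleach mean; post-bleach frames are fit
    with I(t') = I0 + A·(1 - exp(-t'/τ)) where t' is time since the bleach.
    Mobile fraction = (I0 + A - I_bleach)/(1 - I_bleach) with I_bleach = I0
    (the fitted bleach-depth intercept); half-time = τ·ln2.  A fit that fails
    to converge returns ``FrapFit(converged=False)`` with parameters absent.
    """
    b = trace.bleach_index
    if b < 3:
        raise ValueError("need >= 3 pre-bleach frames")
    if len(trace.time_s) - b < 10:
        raise ValueError("need >= 10 post-bleach frames")
    pre_mean = float(trace.intensity[:b].mean())
    if pre_mean <= 0:
        raise ValueError("non-positive pre-bleach intensity")
    y = trace.intensity / pre_mean
    t = trace.time_s - trace.time_s[b]
    yp, tp = y[b:], t[b:]

    i0_guess = float(yp[0])
    a_guess = max(float(yp[-1] - yp[0]), 1e-6)
    tau_guess = max(float(tp[-1] / 5.0), 1e-6)

    def model(tt, i0, a, tau):
        return i0 + a * (1.0 - np.exp(-tt / tau))

    try:
        popt, _ = optimize.curve_fit(
            model,
            tp,
            yp,
            p0=(i0_guess, a_guess, tau_guess),
            bounds=([0.0, 0.0, 1e-9], [1.5, 1.5, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return FrapFit(converged=False)
    i0, a, tau = (float(v) for v in popt)
    if 1.0 - i0 <= 1e-9:  # no bleach depth to recover from
        return FrapFit(converged=False)
    mobile = (i0 + a - i0) / (1.0 - i0)  # = A / (1 - I_bleach)
    mobile = float(np.clip(mobile, 0.0, 1.0))
    resid = yp - model(tp, *popt)
    return FrapFit(
        converged=True,
        mobile_fraction=mobile,
        half_time_s=tau * np.log(2.0),
        tau_s=tau,
        i_bleach=i0,
        plateau=i0 + a,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def read_tiff(path: str | Path, pixel_size_um: float, channel: str = "other") -> FluorescenceImage:
    """Read a single-page TIFF (or the first page of a stack) as an image."""
    data = tifffile.imread(str(path))
    if data.ndim == 3:
        data = data[0]
    return FluorescenceImage(data=np.asarray(data, float), pixel_size_um=pixel_size_um, channel=channel)
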