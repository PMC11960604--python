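"""Two-compartment (tissue vs CSF) partial-volume correction.

Scanner resolution smears activity across tissue boundaries, diluting
gray-matter signal into adjacent CSF where the tracer concentration is
~0.  The classical two-compartment (Meltzer-type) correction undoes
this dilution by dividing the observed image by the point-spread-blurred
brain-tissue fraction: where a voxel is only 70% tissue after blurring,
its observed value is scaled up by 1/0.7.  Voxels whose tissue fraction
falls below a floor are suppressed (set to NaN) rather than amplified
into noise.

The correction accounts for within-subject regional atrophy when the
tissue mask comes from the subject's own segmentation; it does not
attempt to separate gray from white matter (that is the 3-compartment
variant, out of scope here).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["PsfModel", "smooth_mask", "pvc_two_compartment", "correct_roi_values"]

log = logging.getLogger(__name__)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PsfModel:
    """Gaussian point-spread function, FWHM in mm per axis."""

    fwhm_mm: tuple[float, float, float] = (6.0, 6.0, 6.0)
    truncate_sigmas: float = 4.0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fwhm_mm):
            raise ValueError("PSF FWHM must be positive on every axis")

    @classmethod
    def isotropic(cls, fwhm_mm: float) -> "PsfModel":
        return cls((fwhm_mm,) * 3)

    def sigma_voxels(self, voxel_sizes) -> np.ndarray:
        vs = np.asarray(voxel_sizes, float)
        if np.any(vs <= 0):
            raise ValueError("voxel sizes must be positive")
        return np.asarray(self.fwhm_mm) * _FWHM_TO_SIGMA / vs


def smooth_mask(mask: np.ndarray, psf: PsfModel, voxel_sizes) -> np.ndarray:
    """PSF-blurred fractional tissue map in [0, 1].

    Convolution uses zero padding, then renormalizes by the blurred
    all-ones mask so that edge attenuation from the padding cancels and
    an all-ones mask maps to all ones everywhere.
    """
    m = np.asarray(mask, float)
    if not np.isin(np.unique(m), (0.0, 1.0)).all():
        raise ValueError("mask must be binary")
    sig = psf.sigma_voxels(voxel_sizes)
    if np.all(sig == 0):
        return m.copy()
    blurred = gaussian_filter(m, sigma=sig, mode="constant",
                              truncate=psf.truncate_sigmas)
    norm = gaussian_filter(np.ones_like(m), sigma=sig, mode="constant",
                           truncate=psf.truncate_sigmas)
    return np.clip(blurred / norm, 0.0, 1.0)


def pvc_two_compartment(image: np.ndarray, tissue_mask: np.ndarray, psf: PsfModel,
                        floor: float = 0.2, voxel_sizes=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Divide a static image by the blurred tissue fraction.

    ``corrected(v) = image(v) / fraction(v)`` where the PSF-blurred
    tissue fraction is at least ``floor``; voxels below the floor are
    set to NaN and counted in the log.
    """
    image = np.asarray(image, float)
    tissue_mask = np.asarray(tissue_mask)
    if image.shape != tissue_mask.shape:
        raise ValueError("image and tissue mask grids must match")
    if not 0 < floor < 1:
        raise ValueError(f"floor must lie in (0, 1), got {floor}")
    if not tissue_mask.any():
        raise ValueError("tissue mask is empty")
    frac = smooth_mask(tissue_mask, psf, voxel_sizes)
    ok = frac >= floor
    out = np.full_like(image, np.nan)
    out[ok] = image[ok] / frac[ok]
    n_sup = int(out.size - ok.sum())
    if n_sup:
        log.info("two-compartment PVC: %d/%d voxels below fraction floor %.3g "
                 "suppressed", n_sup, out.size, floor)
    return out


def correct_roi_values(values, tissue_fraction, floor: float = 0.2) -> np.ndarray:
    """The same dilution correction at ROI granularity.

    When only regional means and regional tissue fractions are
    available (no images), the corrected regional value is
    ``value / fraction``, with fractions below the floor rejected.
    """
    values = np.asarray(values, float)
    frac = np.asarray(tissue_fraction, float)
    if values.shape != frac.shape:
        raise ValueError("values and tissue fractions must align")
    if np.any((frac < floor) | (frac > 1.0)):
        raise ValueError(f"tissue fractions must lie in [{floor}, 1]")
    return values / frac
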