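"""4-D dynamic image container, NIfTI I/O and regional TAC extraction."""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .frames import FrameSchedule, TimeActivityCurve, window_average_image

__all__ = ["DynamicImage", "extract_roi_tac", "load_dynamic", "save_static"]


@dataclass
class DynamicImage:
    """Voxel array indexed (x, y, z, frame) with its timing and geometry.

    ``voxel_sizes`` are mm; ``affine`` defaults to a scaled identity when
    images are created synthetically rather than loaded from disk.
    """

    data: np.ndarray
    voxel_sizes: tuple[float, float, float]
    schedule: FrameSchedule
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 4:
            raise ValueError(f"dynamic image must be 4-D, got shape {self.data.shape}")
        if self.data.shape[-1] != len(self.schedule):
            raise ValueError(
                f"frame axis length {self.data.shape[-1]} does not match "
                f"schedule of {len(self.schedule)} frames")
        if any(v <= 0 for v in self.voxel_sizes):
            raise ValueError("voxel sizes must be positive")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_sizes) + [1.0])

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_sizes))

    def window_average(self, window) -> np.ndarray:
        """Static 3-D image: duration-weighted mean over the window (min)."""
        return window_average_image(self.data, self.schedule, window)

    def save(self, path, sidecar_path=None) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms(tuple(self.voxel_sizes) + (1.0,))
        nib.save(img, str(path))
        if sidecar_path is not None:
            self.schedule.to_sidecar(sidecar_path)


def load_dynamic(path, sidecar_path) -> DynamicImage:
    """Load a 4-D NIfTI plus its frame-timing sidecar (JSON or TSV)."""
    img = nib.load(str(path))
    schedule = FrameSchedule.from_sidecar(sidecar_path)
    zooms = img.header.get_zooms()[:3]
    return DynamicImage(np.asarray(img.dataobj, float), tuple(float(z) for z in zooms),
                        schedule, affine=np.asarray(img.affine))


def load_labels(path) -> np.ndarray:
    """Load a 3-D integer label map."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj).astype(int)


def save_static(data: np.ndarray, voxel_sizes, path, affine=None) -> None:
    if affine is None:
        affine = np.diag(list(voxel_sizes) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, np.float32), affine)
    img.header.set_zooms(tuple(voxel_sizes))
    nib.save(img, str(path))


def extract_roi_tac(image: DynamicImage, labels: np.ndarray, label_set,
                    name: str = "") -> TimeActivityCurve:
    """Mean TAC over all voxels whose label is in ``label_set``.

    Per-frame unweighted voxel mean; the returned curve carries the voxel
    count and physical volume of the region.
    """
    labels = np.asarray(labels)
    if labels.shape != image.data.shape[:3]:
        raise ValueError(
            f"label map shape {labels.shape} does not match image grid {image.data.shape[:3]}")
    label_set = [int(v) for v in np.atleast_1d(label_set)]
    if not label_set:
        raise ValueError("label_set must be nonempty")
    present = set(np.unique(labels).tolist())
    missing = [v for v in label_set if v not in present]
    if missing:
        raise ValueError(f"labels not present in label map: {missing}")
    mask = np.isin(labels, label_set)
    values = image.data[mask].mean(axis=0)
    n_vox = int(mask.sum())
    return TimeActivityCurve.from_schedule(
        image.schedule, values, voxel_count=n_vox,
        volume_mm3=n_vox * image.voxel_volume_mm3, name=name)
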