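"""Reading, writing, validation and smoothing of normalized gray-matter maps.

A *gray-matter (GM) probability map* is a 3D volume in which each voxel holds
the probability (or proportion) of that voxel being gray matter, as produced
by tissue segmentation of a T1-weighted MRI and spatial normalization into a
common template space.  All volumes taking part in one matching experiment
must live in the same template space, i.e. share grid shape and voxel size.

This module provides the two on-disk interfaces of the package — NIfTI-1
volumes and a CSV dataset manifest — plus the isotropic Gaussian smoothing
that finishes the preprocessing chain before matching.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

#: FWHM of an isotropic Gaussian = 2*sqrt(2*ln 2) * sigma.
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: Voxel values may stray this far outside [0, 1] (float noise from the
#: segmentation) and are silently clipped; anything further is an error.
GM_VALUE_TOLERANCE = 1e-6

#: Gaussian kernels are truncated at this many standard deviations.
KERNEL_TRUNCATE_SD = 4.0


class InvalidGMMapError(ValueError):
    """Raised when a volume cannot be interpreted as a GM probability map."""


class GridMismatchError(ValueError):
    """Raised when two volumes do not share grid shape and voxel size."""


ScanKey = tuple[str, int, int]  # (subject_id, visit_id, scan_id)


@dataclass
class GMVolume:
    """One spatially normalized GM probability volume with its identity.

    Parameters
    ----------
    subject_id : str
        Identifier of the scanned subject.
    visit_id : int
        1-based ordinal of the imaging session (visit).
    scan_id : int
        1-based ordinal of the scan within the visit; "the second scan in
        the first visit" is ``visit_id=1, scan_id=2``.
    data : ndarray
        3D float array of per-voxel GM probability, values in [0, 1].
    voxel_size_mm : tuple of float
        Physical voxel edge lengths in millimetres, all positive.
    """

    subject_id: str
    visit_id: int
    scan_id: int
    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = _validate_gm_data(np.asarray(self.data))
        if self.visit_id < 1 or self.scan_id < 1:
            raise ValueError("visit_id and scan_id are 1-based ordinals")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size_mm must be 3 positive lengths, got {vs}")
        self.voxel_size_mm = vs

    @property
    def key(self) -> ScanKey:
        return (self.subject_id, self.visit_id, self.scan_id)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "GMVolume") -> bool:
        return self.shape == other.shape and np.allclose(
            self.voxel_size_mm, other.voxel_size_mm
        )


def _validate_gm_data(data: np.ndarray) -> np.ndarray:
    if data.ndim != 3:
        raise InvalidGMMapError(f"expected a 3D volume, got {data.ndim} dimensions")
    data = data.astype(np.float32, copy=False)
    if not np.all(np.isfinite(data)):
        raise InvalidGMMapError("volume contains non-finite voxel values")
    lo = float(data.min())
    hi = float(data.max())
    if lo < -GM_VALUE_TOLERANCE or hi > 1.0 + GM_VALUE_TOLERANCE:
        raise InvalidGMMapError(
            f"voxel values outside [0,1] beyond tolerance: min={lo:g}, max={hi:g}"
        )
    if lo < 0.0 or hi > 1.0:
        data = np.clip(data, 0.0, 1.0)
    return data


def read_gm_volume(
    path: str | Path, subject_id: str, visit_id: int, scan_id: int
) -> GMVolume:
    """Load a GM probability volume from a NIfTI-1 file and validate it.

    Values outside [0, 1] by at most ``GM_VALUE_TOLERANCE`` are clipped;
    larger excursions raise :class:`InvalidGMMapError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise InvalidGMMapError(
            f"{path}: expected a 3D scalar image, got shape {data.shape}"
        )
    zooms = img.header.get_zooms()[:3]
    return GMVolume(
        subject_id=subject_id,
        visit_id=int(visit_id),
        scan_id=int(scan_id),
        data=np.asarray(data, dtype=np.float32),
        voxel_size_mm=tuple(float(z) for z in zooms),
    )


def write_gm_volume(vol: GMVolume, path: str | Path) -> None:
    """Write a volume as single-file NIfTI-1 (.nii or .nii.gz), float32."""
    path = Path(path)
    affine = np.diag(list(vol.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(vol.data.astype(np.float32), affine)
    img.header.set_zooms(vol.voxel_size_mm)
    nib.save(img, str(path))


def smooth_volume(vol: GMVolume, fwhm_mm: float) -> GMVolume:
    """Smooth with an isotropic Gaussian of the given FWHM (in mm).

    The kernel standard deviation per axis is
    ``sigma_vox = fwhm_mm / (voxel_size_mm * 2*sqrt(2*ln 2))``, so the kernel
    is isotropic in physical space even on anisotropic grids.  The result is
    clipped back to [0, 1] (convolution of values in [0,1] stays in [0,1] up
    to float error).  ``fwhm_mm = 0`` returns an identical copy.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        smoothed = vol.data.copy()
    else:
        sigma_vox = [fwhm_mm / (v * FWHM_TO_SIGMA) for v in vol.voxel_size_mm]
        smoothed = ndimage.gaussian_filter(
            vol.data.astype(np.float64), sigma=sigma_vox, truncate=KERNEL_TRUNCATE_SD
        )
        smoothed = np.clip(smoothed, 0.0, 1.0).astype(np.float32)
    return GMVolume(
        subject_id=vol.subject_id,
        visit_id=vol.visit_id,
        scan_id=vol.scan_id,
        data=smoothed,
        voxel_size_mm=vol.voxel_size_mm,
    )


@dataclass
class DatasetIndex:
    """The collection of volumes of one experiment, queryable by identity.

    Enforces uniqueness of (subject, visit, scan) triples and a common grid,
    and exposes the per-subject visit structure used by the genuine-pair
    combinatorics: for each subject the number of visits V and the list of
    scans per visit (m_1 .. m_V), and the histogram n_V counting subjects
    with exactly V visits.
    """

    volumes: list[GMVolume] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_key: dict[ScanKey, GMVolume] = {}
        for vol in self.volumes:
            self._register(vol)

    def _register(self, vol: GMVolume) -> None:
        if vol.key in self._by_key:
            raise ValueError(f"duplicate (subject, visit, scan) triple: {vol.key}")
        if self.volumes and not self.volumes[0].same_grid(vol):
            ref = self.volumes[0]
            raise GridMismatchError(
                f"volume {vol.key} grid {vol.shape}/{vol.voxel_size_mm} differs "
                f"from {ref.key} grid {ref.shape}/{ref.voxel_size_mm}"
            )
        self._by_key[vol.key] = vol

    def add(self, vol: GMVolume) -> None:
        self._register(vol)
        self.volumes.append(vol)

    def __len__(self) -> int:
        return len(self.volumes)

    def __iter__(self) -> Iterator[GMVolume]:
        return iter(self.volumes)

    def get(self, subject_id: str, visit_id: int, scan_id: int) -> GMVolume:
        key = (subject_id, visit_id, scan_id)
        try:
            return self._by_key[key]
        except KeyError:
            raise KeyError(f"no volume for {key} in index") from None

    def resolve(self, key: ScanKey) -> GMVolume:
        return self.get(*key)

    @property
    def subjects(self) -> list[str]:
        """Distinct subject ids, sorted."""
        return sorted({v.subject_id for v in self.volumes})

    def visits(self, subject_id: str) -> list[int]:
        return sorted(
            {v.visit_id for v in self.volumes if v.subject_id == subject_id}
        )

    def scans(self, subject_id: str, visit_id: int) -> list[int]:
        return sorted(
            v.scan_id
            for v in self.volumes
            if v.subject_id == subject_id and v.visit_id == visit_id
        )

    def visit_structure(self, subject_id: str) -> list[int]:
        """Scans-per-visit list (m_1 .. m_V) for one subject, visit order."""
        return [len(self.scans(subject_id, v)) for v in self.visits(subject_id)]

    def n_visits_histogram(self) -> dict[int, int]:
        """n_V: number of subjects having exactly V visits."""
        hist: dict[int, int] = {}
        for s in self.subjects:
            v = len(self.visits(s))
            hist[v] = hist.get(v, 0) + 1
        return hist


MANIFEST_COLUMNS = ("path", "subject_id", "visit_id", "scan_id")


def write_manifest(rows: Iterable[tuple[str, str, int, int]], path: str | Path) -> None:
    """Write a dataset manifest CSV (path, subject_id, visit_id, scan_id)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for row in rows:
            writer.writerow(row)


def load_dataset(manifest_path: str | Path) -> DatasetIndex:
    """Load every volume listed in a manifest CSV into a :class:`DatasetIndex`.

    Relative volume paths are resolved against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    index = DatasetIndex()
    with open(manifest_path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(MANIFEST_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        for row in reader:
            p = Path(row["path"])
            if not p.is_absolute():
                p = base / p
            index.add(
                read_gm_volume(
                    p, row["subject_id"], int(row["visit_id"]), int(row["scan_id"])
                )
            )
    if not index.volumes:
        raise ValueError(f"manifest {manifest_path} lists no volumes")
    return index


def smooth_dataset(index: DatasetIndex, fwhm_mm: float) -> DatasetIndex:
    """Smooth every volume of an index; returns a new index."""
    return DatasetIndex([smooth_volume(v, fwhm_mm) for v in index])
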