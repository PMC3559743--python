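"""Synthetic normalized-GM phantom datasets with subject/visit/scan structure.

Longitudinal MRI biometrics needs data in which the same head was imaged
several times per session and in sessions separated by long intervals.  The
generator here emulates that structure without anatomical realism: every
subject owns a stable GM pattern (a shared cortical-shell base plus a
subject-unique smooth random field), each visit adds a smooth additive drift
field (intra-class variability: repositioning, scanner state, slow anatomy
change), and each scan adds voxelwise acquisition noise.  All three layers
are seeded hierarchically so any single volume is reproducible in isolation.

The amplitude hierarchy (subject pattern >> visit drift > scan noise) is what
makes within-subject distances smaller than between-subject distances, which
is the regime the matching method assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml
from scipy import ndimage

from .volumes import DatasetIndex, GMVolume, write_gm_volume, write_manifest

# Seed-stream tags: keep template / visit-drift / scan-noise streams disjoint.
_TAG_TEMPLATE = 0
_TAG_VISIT = 1
_TAG_SCAN = 2


@dataclass
class PhantomConfig:
    """All parameters of the synthetic GM phantom generator.

    Defaults mirror a 150-subject longitudinal cohort in which every subject
    was imaged at 2 visits with 3 scans each, on a coarse 32x32x32 grid of
    2 mm voxels.  The variation amplitudes are dimensionless GM-probability
    units: ``subject_amplitude`` scales the subject-unique anatomy field,
    ``visit_drift_sd`` the per-visit smooth drift, and ``scan_noise_sd`` the
    per-scan white noise.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_subjects: int = 150
    visits_per_subject: int = 2
    scans_per_visit: int = 3
    subject_amplitude: float = 0.2
    visit_drift_sd: float = 0.05
    scan_noise_sd: float = 0.02
    smoothness_vox: float = 2.0
    master_seed: int = 1

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if any(g < 1 for g in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError(f"grid_shape must be 3 positive counts: {self.grid_shape}")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2 for any matching experiment")
        if self.visits_per_subject < 1 or self.scans_per_visit < 1:
            raise ValueError("visits_per_subject and scans_per_visit must be >= 1")
        for name in ("subject_amplitude", "visit_drift_sd", "scan_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.smoothness_vox < 0:
            raise ValueError("smoothness_vox must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def subject_id(self, subject_index: int) -> str:
        return f"S{subject_index:04d}"


@dataclass
class SubjectTemplate:
    """A subject's noise-free GM pattern on the phantom grid."""

    subject_id: str
    subject_index: int
    template: np.ndarray


def brain_shell_base(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Shared brain-like support: an ellipsoidal cortical shell.

    GM probability is ~0.8 on an ellipsoidal shell (the cortex analogue,
    between 55% and 95% of the ellipsoid radius) and 0 outside.  All
    subjects share this base; individual anatomy is added on top of it.
    """
    shape = np.asarray(grid_shape, dtype=float)
    center = (shape - 1) / 2.0
    semi_axes = 0.45 * shape  # ellipsoid fills ~90% of the grid extent
    grids = np.meshgrid(*(np.arange(n, dtype=float) for n in grid_shape), indexing="ij")
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    r = np.sqrt(r2)
    base = np.zeros(grid_shape, dtype=np.float64)
    base[(r >= 0.55) & (r <= 0.95)] = 0.8
    return base


def shell_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Boolean mask of the in-shell (GM > 0) voxels of the shared base."""
    return brain_shell_base(grid_shape) > 0


def smooth_random_field(
    rng: np.random.Generator,
    grid_shape: tuple[int, int, int],
    smoothness_vox: float,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Zero-mean, unit-sd smooth Gaussian random field.

    White Gaussian noise is smoothed by a Gaussian of sd ``smoothness_vox``
    (spatially coherent, anatomy-like variation rather than salt-and-pepper)
    and then standardized to zero mean and unit sample sd over ``mask``
    (the brain shell by default).
    """
    noise = rng.standard_normal(grid_shape)
    if smoothness_vox > 0:
        noise = ndimage.gaussian_filter(noise, sigma=smoothness_vox)
    region = noise[mask] if mask is not None else noise
    sd = region.std()
    if sd == 0:  # degenerate (e.g. 1-voxel grid); leave unscaled
        return noise - region.mean()
    return (noise - region.mean()) / sd


def _rng(config: PhantomConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.master_seed, *key]))


def make_subject_template(
    config: PhantomConfig, subject_index: int
) -> SubjectTemplate:
    """Build subject ``subject_index``'s stable GM pattern.

    ``template = clip(base + subject_amplitude * field_s, 0, 1)`` where
    ``field_s`` is a smooth unit-sd random field seeded deterministically
    from (master_seed, subject_index).
    """
    if not 0 <= subject_index < config.n_subjects:
        raise IndexError(
            f"subject_index {subject_index} out of range [0, {config.n_subjects})"
        )
    base = brain_shell_base(config.grid_shape)
    mask = base > 0
    rng = _rng(config, _TAG_TEMPLATE, subject_index)
    fld = smooth_random_field(rng, config.grid_shape, config.smoothness_vox, mask)
    template = np.clip(base + config.subject_amplitude * fld, 0.0, 1.0)
    return SubjectTemplate(
        subject_id=config.subject_id(subject_index),
        subject_index=subject_index,
        template=template,
    )


def sample_scan(
    tpl: SubjectTemplate, visit_id: int, scan_id: int, config: PhantomConfig
) -> GMVolume:
    """Draw one scan of a subject at a given visit.

    Two degradation layers are added to the subject template: a smooth
    per-visit drift field (identical for every scan of the visit; models
    session-to-session change) and per-scan voxelwise white noise (models
    acquisition noise from the scanner electronics).
    """
    if visit_id < 1 or scan_id < 1:
        raise ValueError("visit_id and scan_id are 1-based ordinals")
    data = tpl.template.astype(np.float64, copy=True)
    mask = shell_mask(config.grid_shape)
    if config.visit_drift_sd > 0:
        drift_rng = _rng(config, _TAG_VISIT, tpl.subject_index, visit_id)
        drift = smooth_random_field(
            drift_rng, config.grid_shape, config.smoothness_vox, mask
        )
        data += config.visit_drift_sd * drift
    if config.scan_noise_sd > 0:
        scan_rng = _rng(config, _TAG_SCAN, tpl.subject_index, visit_id, scan_id)
        data += config.scan_noise_sd * scan_rng.standard_normal(config.grid_shape)
    return GMVolume(
        subject_id=tpl.subject_id,
        visit_id=visit_id,
        scan_id=scan_id,
        data=np.clip(data, 0.0, 1.0).astype(np.float32),
        voxel_size_mm=config.voxel_size_mm,
    )


def build_dataset(config: PhantomConfig) -> DatasetIndex:
    """Generate the full phantom dataset in memory.

    Produces ``n_subjects * visits_per_subject * scans_per_visit`` volumes in
    deterministic (subject, visit, scan) order.
    """
    index = DatasetIndex()
    for s in range(config.n_subjects):
        tpl = make_subject_template(config, s)
        for visit in range(1, config.visits_per_subject + 1):
            for scan in range(1, config.scans_per_visit + 1):
                index.add(sample_scan(tpl, visit, scan, config))
    return index


def generate_dataset(config: PhantomConfig, out_dir: str | Path) -> DatasetIndex:
    """Generate the phantom dataset and write it to disk.

    Writes one uncompressed ``.nii`` per volume plus ``manifest.csv`` under
    ``out_dir`` and returns the in-memory index.  Uncompressed NIfTI keeps
    reruns with the same config byte-identical (gzip streams embed
    timestamps).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index = build_dataset(config)
    rows: list[tuple[str, str, int, int]] = []
    for vol in index:
        name = f"{vol.subject_id}_v{vol.visit_id}_s{vol.scan_id}.nii"
        write_gm_volume(vol, out_dir / name)
        rows.append((name, vol.subject_id, vol.visit_id, vol.scan_id))
    write_manifest(rows, out_dir / "manifest.csv")
    return index
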