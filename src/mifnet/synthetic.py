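"""Synthetic fixtures with the statistical structure the pipeline assumes.

Two generators:

* :func:`make_synthetic_scan` writes a small MetaImage CT volume with a noisy
  lung-like background (Gaussian around -800 HU) and additive bright
  spheroids standing in for nodules (~ +50 HU soft-tissue attenuation),
  together with a LUNA16-dialect candidates table — one positive row per
  spheroid and ``n_negatives`` background rows kept at least two radii from
  every spheroid.  This exercises the full MetaImage -> voxel -> patch
  pipeline end to end.

* :func:`make_patch_dataset` emits labelled 50x50 patches directly:
  positives carry a centered bright disc of controllable contrast
  (``separation`` x the noise standard deviation), negatives the same
  background with either nothing or an off-center low-amplitude distractor.
  ``separation = 0`` makes the classes identically distributed.

No anatomical realism is attempted; every random draw flows from a single
integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import SimpleITK as sitk


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic CT scan plus its annotation table.

    ``volume_shape`` is (x, y, z) voxels; ``spacing`` (x, y, z) mm;
    ``origin`` (x, y, z) mm.  Each nodule is (world_xyz, radius_mm,
    intensity_hu).
    """

    volume_shape: Tuple[int, int, int] = (120, 120, 40)
    spacing: Tuple[float, float, float] = (0.7, 0.7, 1.25)
    origin: Tuple[float, float, float] = (-42.0, -42.0, -25.0)
    background_hu: float = -800.0
    noise_sd_hu: float = 40.0
    nodules: Tuple[Tuple[Tuple[float, float, float], float, float], ...] = ()
    n_negatives: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.volume_shape):
            raise ValueError(f"empty volume shape {self.volume_shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        lo = self.origin
        hi = tuple(o + (n - 1) * s for o, n, s in
                   zip(self.origin, self.volume_shape, self.spacing))
        for center, radius, _ in self.nodules:
            if radius <= 0:
                raise ValueError(f"nodule radius must be > 0, got {radius}")
            for axis in range(3):
                if not lo[axis] <= center[axis] <= hi[axis]:
                    raise ValueError(
                        f"nodule center {center} outside the volume "
                        f"(axis {'xyz'[axis]}, bounds [{lo[axis]}, {hi[axis]}])")


def default_scan_spec(seed: int = 0, n_nodules: int = 3,
                      n_negatives: int = 15) -> SyntheticSpec:
    """A small scan with seeded, well-separated nodules of 3-6 mm radius."""
    rng = np.random.default_rng(seed)
    base = SyntheticSpec(seed=seed)
    lo = np.array(base.origin)
    extent = (np.array(base.volume_shape) - 1) * np.array(base.spacing)
    nodules = []
    for _ in range(n_nodules):
        # keep centers in the interior so patches stay mostly inside
        frac = rng.uniform(0.25, 0.75, size=3)
        center = tuple(np.round(lo + frac * extent, 2))
        radius = float(np.round(rng.uniform(3.0, 6.0), 2))
        intensity = float(np.round(rng.uniform(700.0, 900.0), 1))
        nodules.append((center, radius, intensity))
    return SyntheticSpec(nodules=tuple(nodules), n_negatives=n_negatives,
                         seed=seed)


def make_synthetic_scan(spec: SyntheticSpec, out_dir: str | Path,
                        series_id: str = "synthetic_scan"
                        ) -> Tuple[Path, Path]:
    """Write .mhd/.raw plus a candidates CSV; returns (header, csv) paths.

    The voxel field is Gaussian noise around the background attenuation with
    each spheroid added on top; negatives are sampled uniformly at least two
    radii away from every nodule center.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.volume_shape
    voxels = rng.normal(spec.background_hu, spec.noise_sd_hu,
                        size=(nz, ny, nx))

    zc, yc, xc = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                             indexing="ij")
    world = {
        "x": spec.origin[0] + xc * spec.spacing[0],
        "y": spec.origin[1] + yc * spec.spacing[1],
        "z": spec.origin[2] + zc * spec.spacing[2],
    }
    for center, radius, intensity in spec.nodules:
        dist2 = ((world["x"] - center[0]) ** 2 + (world["y"] - center[1]) ** 2
                 + (world["z"] - center[2]) ** 2)
        voxels += intensity * (dist2 <= radius ** 2)

    image = sitk.GetImageFromArray(voxels.astype(np.float32))
    image.SetOrigin(spec.origin)
    image.SetSpacing(spec.spacing)
    header_path = out_dir / f"{series_id}.mhd"
    sitk.WriteImage(image, str(header_path), useCompression=False)

    rows = []
    for center, _, _ in spec.nodules:
        rows.append({"seriesuid": series_id, "coordX": center[0],
                     "coordY": center[1], "coordZ": center[2], "class": 1})
    lo = np.array(spec.origin)
    hi = lo + (np.array(spec.volume_shape) - 1) * np.array(spec.spacing)
    placed = 0
    attempts = 0
    while placed < spec.n_negatives:
        attempts += 1
        if attempts > 10000 * max(spec.n_negatives, 1):
            raise RuntimeError("could not place negatives away from nodules")
        point = rng.uniform(lo, hi)
        clear = all(
            np.linalg.norm(point - np.array(center)) >= 2 * radius
            for center, radius, _ in spec.nodules)
        if clear:
            rows.append({"seriesuid": series_id,
                         "coordX": round(float(point[0]), 2),
                         "coordY": round(float(point[1]), 2),
                         "coordZ": round(float(point[2]), 2), "class": 0})
            placed += 1
    csv_path = out_dir / f"{series_id}_candidates.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return header_path, csv_path


def make_patch_dataset(n_per_class: int, separation: float = 8.0,
                       noise_sd: float = 0.05, seed: int = 0,
                       size: int = 50) -> Tuple[np.ndarray, np.ndarray]:
    """Directly generate a balanced labelled patch set.

    Returns ``(images, labels)`` with ``2 * n_per_class`` patches of shape
    ``(size, size)`` in [0, 1].  Positives hold a centered disc of radius
    4-12 px and amplitude ``separation * noise_sd`` over a noisy background;
    negatives hold either no structure or an off-center distractor at a
    quarter of that amplitude.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    background_level = 0.3
    amplitude = separation * noise_sd
    yy, xx = np.mgrid[:size, :size]
    images = np.empty((2 * n_per_class, size, size))
    labels = np.repeat([1, 0], n_per_class)
    center = (size - 1) / 2
    for i, label in enumerate(labels):
        img = rng.normal(background_level, noise_sd, size=(size, size))
        radius = rng.uniform(4, 12)
        if label == 1:
            disc = (xx - center) ** 2 + (yy - center) ** 2 <= radius ** 2
            img += amplitude * disc
        elif rng.random() < 0.5:
            # off-center faint distractor; absent entirely otherwise
            off = rng.uniform(0.6, 0.9) * size / 2
            angle = rng.uniform(0, 2 * np.pi)
            cx = center + off * np.cos(angle)
            cy = center + off * np.sin(angle)
            disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2
            img += 0.25 * amplitude * disc
        images[i] = np.clip(img, 0.0, 1.0)
    order = rng.permutation(len(labels))
    return images[order], labels[order]
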