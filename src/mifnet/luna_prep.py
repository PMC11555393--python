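"""CT candidate-patch preprocessing.

Reads MetaImage (.mhd/.raw) CT volumes, converts world-frame (mm) candidate
coordinates to voxel indices, windows Hounsfield intensities to [0, 1], crops
50x50 axial patches around each candidate, and rebalances the heavily skewed
nodule/negative classes by seeded negative undersampling plus rotation
augmentation of the positives.

Axis convention: voxel arrays are indexed ``(z, y, x)`` (SimpleITK's array
order); world coordinates, origins and spacings are ``(x, y, z)`` in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import SimpleITK as sitk
from PIL import Image

from .config import ConfigurationError

#: Hounsfield window spanning air (-1000 HU) to soft tissue / calcification
#: (+400 HU) — the usual lung-CT display window.
HU_WINDOW = (-1000.0, 400.0)


class FormatError(ValueError):
    """Raised for inconsistent or unreadable volume files."""


class OutOfBoundsError(ValueError):
    """Raised when a coordinate falls outside the volume; carries the axis."""

    def __init__(self, message: str, axis: str):
        super().__init__(message)
        self.axis = axis


class BalancingError(ValueError):
    """Raised when a class needed for rebalancing is empty."""


@dataclass
class VolumeRecord:
    """A CT volume with its world-frame geometry.

    ``voxels`` is (z, y, x) in Hounsfield units; ``origin`` and ``spacing``
    are (x, y, z) in mm.
    """

    voxels: np.ndarray
    origin: Tuple[float, float, float]
    spacing: Tuple[float, float, float]
    series_id: str = ""

    def __post_init__(self) -> None:
        if self.voxels.size == 0:
            raise FormatError("voxel array is empty")
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape_xyz(self) -> Tuple[int, int, int]:
        nz, ny, nx = self.voxels.shape
        return (nx, ny, nz)


@dataclass(frozen=True)
class Annotation:
    """One candidate row: world-frame position plus binary label."""

    series_id: str
    world_xyz: Tuple[float, float, float]
    label: int  # 1 = nodule/malignant, 0 = negative/benign
    diameter_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if not all(np.isfinite(self.world_xyz)):
            raise ValueError(f"non-finite coordinates {self.world_xyz}")


@dataclass
class PatchSample:
    """A 50x50 grayscale patch in [0, 1] with label and provenance."""

    image: np.ndarray
    label: int
    series_id: str = ""
    center_voxel: Tuple[int, int, int] = (0, 0, 0)  # (x, y, z)

    def __post_init__(self) -> None:
        if self.image.ndim != 2:
            raise ValueError(f"patch must be 2D, got shape {self.image.shape}")
        lo, hi = float(self.image.min()), float(self.image.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"patch values outside [0, 1]: [{lo}, {hi}]")


def read_metaimage(header_path: str | Path) -> VolumeRecord:
    """Read a MetaImage header/raw pair into a :class:`VolumeRecord`."""
    header_path = Path(header_path)
    if not header_path.exists():
        raise FormatError(f"header file not found: {header_path}")
    # verify the raw payload before handing to SimpleITK, to fail with a
    # precise message naming the offending field
    header = {}
    for line in header_path.read_text().splitlines():
        if "=" in line:
            key, val = (s.strip() for s in line.split("=", 1))
            header[key] = val
    if "ElementDataFile" in header:
        raw_name = header["ElementDataFile"]
        raw_path = header_path.parent / raw_name
        if raw_name != "LOCAL" and not raw_path.exists():
            raise FormatError(f"ElementDataFile missing: {raw_path}")
        if "DimSize" in header and raw_name != "LOCAL":
            dims = [int(d) for d in header["DimSize"].split()]
            elem = header.get("ElementType", "MET_SHORT")
            bytes_per = {"MET_CHAR": 1, "MET_UCHAR": 1, "MET_SHORT": 2,
                         "MET_USHORT": 2, "MET_INT": 4, "MET_UINT": 4,
                         "MET_FLOAT": 4, "MET_DOUBLE": 8}.get(elem, 2)
            expected = int(np.prod(dims)) * bytes_per
            actual = raw_path.stat().st_size
            if actual != expected:
                raise FormatError(
                    f"DimSize {dims} x {elem} implies {expected} bytes but "
                    f"{raw_path.name} holds {actual}")
    image = sitk.ReadImage(str(header_path))
    voxels = sitk.GetArrayFromImage(image)  # (z, y, x)
    return VolumeRecord(
        voxels=voxels.astype(np.float64),
        origin=tuple(image.GetOrigin()),
        spacing=tuple(image.GetSpacing()),
        series_id=header_path.stem,
    )


def world_to_voxel(world_xyz: Sequence[float],
                   origin: Sequence[float],
                   spacing: Sequence[float],
                   shape_xyz: Optional[Sequence[int]] = None
                   ) -> Tuple[int, int, int]:
    """Convert a world-frame (mm) position to the nearest voxel index.

    ``index = round((world - origin) / spacing)`` per axis.  If ``shape_xyz``
    is given, out-of-range indices raise :class:`OutOfBoundsError` naming the
    axis.
    """
    idx = []
    for axis, (w, o, s) in enumerate(zip(world_xyz, origin, spacing)):
        if s <= 0:
            raise ValueError(f"spacing must be positive, got {s}")
        i = int(np.rint((w - o) / s))
        if shape_xyz is not None and not 0 <= i < shape_xyz[axis]:
            name = "xyz"[axis]
            raise OutOfBoundsError(
                f"axis {name}: world {w} -> voxel {i} outside [0, "
                f"{shape_xyz[axis]})", axis=name)
        idx.append(i)
    return tuple(idx)


def voxel_to_world(index_xyz: Sequence[int], origin: Sequence[float],
                   spacing: Sequence[float]) -> Tuple[float, float, float]:
    """Inverse map: ``world = origin + index * spacing``."""
    return tuple(o + i * s for i, o, s in zip(index_xyz, origin, spacing))


def rescale_hu(voxels: np.ndarray, window_low: float = HU_WINDOW[0],
               window_high: float = HU_WINDOW[1]) -> np.ndarray:
    """Clip Hounsfield values to the window and map affinely onto [0, 1]."""
    if window_low >= window_high:
        raise ValueError(f"window_low {window_low} must be < window_high "
                         f"{window_high}")
    clipped = np.clip(voxels, window_low, window_high)
    return (clipped - window_low) / (window_high - window_low)


def extract_patch(volume: VolumeRecord, center_voxel: Sequence[int],
                  size: int = 50) -> PatchSample:
    """Crop a ``size x size`` axial patch centered on a voxel.

    The slice is fixed at the center's z index; regions outside the volume
    are zero-padded (zero = the low end of the Hounsfield window after
    rescaling).
    """
    cx, cy, cz = (int(v) for v in center_voxel)
    nx, ny, nz = volume.shape_xyz
    for value, n, name in ((cx, nx, "x"), (cy, ny, "y"), (cz, nz, "z")):
        if not 0 <= value < n:
            raise OutOfBoundsError(
                f"axis {name}: center {value} outside [0, {n})", axis=name)
    half = size // 2
    y0, x0 = cy - half, cx - half
    patch = np.zeros((size, size))
    ys = slice(max(y0, 0), min(y0 + size, ny))
    xs = slice(max(x0, 0), min(x0 + size, nx))
    patch[ys.start - y0:ys.stop - y0, xs.start - x0:xs.stop - x0] = \
        rescale_hu(volume.voxels[cz, ys, xs])
    return PatchSample(image=patch, label=0, series_id=volume.series_id,
                       center_voxel=(cx, cy, cz))


def patches_from_annotations(volume: VolumeRecord,
                             annotations: Sequence[Annotation],
                             size: int = 50) -> List[PatchSample]:
    """Extract a labelled patch for every annotation of this volume."""
    out = []
    for ann in annotations:
        if ann.series_id and volume.series_id and \
                ann.series_id != volume.series_id:
            continue
        center = world_to_voxel(ann.world_xyz, volume.origin, volume.spacing,
                                volume.shape_xyz)
        patch = extract_patch(volume, center, size)
        patch.label = ann.label
        out.append(patch)
    return out


def read_annotations(path: str | Path) -> List[Annotation]:
    """Read a candidates table (series_id, coordX/Y/Z, class) from CSV."""
    df = pd.read_csv(path)
    required = {"seriesuid", "coordX", "coordY", "coordZ", "class"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"annotation table missing columns: {sorted(missing)}")
    return [Annotation(series_id=str(row["seriesuid"]),
                       world_xyz=(float(row["coordX"]), float(row["coordY"]),
                                  float(row["coordZ"])),
                       label=int(row["class"]))
            for _, row in df.iterrows()]


def _rotate(patch: PatchSample, quarter_turns: int) -> PatchSample:
    return PatchSample(image=np.rot90(patch.image, k=quarter_turns).copy(),
                       label=patch.label, series_id=patch.series_id,
                       center_voxel=patch.center_voxel)


def balance_dataset(positives: Sequence[PatchSample],
                    negatives: Sequence[PatchSample],
                    negative_per_positive: int = 5,
                    rotations: Sequence[int] = (90, 180, 270),
                    seed: int = 0) -> List[PatchSample]:
    """Rebalance classes: undersample negatives, rotate positives.

    Negatives are uniformly undersampled (without replacement where possible)
    to ``negative_per_positive`` per original positive — the default 5 yields
    one nodule patch in every six images before augmentation.  Each positive
    is emitted in its original orientation plus the stated quarter-turn
    rotations.  The combined list is shuffled with the same seed.
    """
    if not positives or not negatives:
        raise BalancingError("both classes must be non-empty")
    if any(r % 90 for r in rotations):
        raise ValueError(f"rotations must be multiples of 90, got {rotations}")
    rng = np.random.default_rng(seed)
    n_keep = min(negative_per_positive * len(positives), len(negatives))
    keep_idx = rng.choice(len(negatives), size=n_keep, replace=False)
    out: List[PatchSample] = [negatives[i] for i in keep_idx]
    for patch in positives:
        out.append(patch)
        out.extend(_rotate(patch, (r // 90) % 4) for r in rotations)
    order = rng.permutation(len(out))
    return [out[i] for i in order]


def export_split(samples: Sequence[PatchSample], out_dir: str | Path,
                 train_fraction: float = 0.8, seed: int = 0
                 ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded shuffle + split; write patches as 8-bit PNGs with manifests.

    Creates ``train/`` and ``test/`` subdirectories, each holding the patch
    images and a ``manifest.csv`` with columns path, label, series_id,
    center_x/y/z.  Returns the two manifests.
    """
    if not samples:
        raise ValueError("no samples to export")
    if not 0 < train_fraction < 1:
        raise ConfigurationError(
            f"train_fraction must lie strictly in (0, 1), got {train_fraction}")
    out_dir = Path(out_dir)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    n_train = int(round(train_fraction * len(samples)))
    manifests = []
    for split, idx in (("train", order[:n_train]), ("test", order[n_train:])):
        split_dir = out_dir / split
        split_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for rank, i in enumerate(idx):
            s = samples[i]
            name = f"patch_{rank:05d}_c{s.label}.png"
            img = np.clip(np.rint(s.image * 255), 0, 255).astype(np.uint8)
            Image.fromarray(img, mode="L").save(split_dir / name)
            rows.append({"path": name, "label": s.label,
                         "series_id": s.series_id,
                         "center_x": s.center_voxel[0],
                         "center_y": s.center_voxel[1],
                         "center_z": s.center_voxel[2]})
        manifest = pd.DataFrame(rows)
        manifest.to_csv(split_dir / "manifest.csv", index=False)
        manifests.append(manifest)
    return tuple(manifests)


def load_patch_dir(split_dir: str | Path) -> Tuple[np.ndarray, np.ndarray]:
    """Load an exported split back into (images, labels) arrays in [0, 1]."""
    split_dir = Path(split_dir)
    manifest = pd.read_csv(split_dir / "manifest.csv")
    images = np.stack([
        np.asarray(Image.open(split_dir / row.path), dtype=np.float64) / 255.0
        for row in manifest.itertuples()])
    return images, manifest["label"].to_numpy()
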