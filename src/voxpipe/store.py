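"""Local folder database with an OMERO-like project/dataset/image hierarchy.

The layout on disk is::

    root/
      <project>/
        <dataset>/
          <image>.tif ...
          attachments/        # results tables linked to images by name prefix

Images are multi-page TIFF files; spatial calibration, axis order and the
image *kind* (intensity / binary / label) travel in the TIFF description so
that a write/read pair is voxel- and calibration-exact and a stored label map
comes back as a :class:`~voxpipe.containers.LabelMap`.  Results tables are
plain CSV (comma separator, header row, ``.`` decimal), linked to their
source image by the ``<image>-`` filename prefix — the simplest faithful
analog of OMERO attachments.

``attachments`` is a reserved name at the dataset level and cannot be used as
a dataset.
"""

from __future__ import annotations

import shutil
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import (
    Calibration,
    ImageInfo,
    ImageRef,
    MultiDimImage,
    VoxelGrid,
    extract_plane,
)
from .errors import StoreError

__all__ = [
    "ImageDatabase",
    "init_db",
    "read_multidim",
    "read_grid",
    "write_grid",
    "read_table",
    "write_table",
    "ImageRef",
    "ImageInfo",
    "Calibration",
    "VoxelGrid",
    "MultiDimImage",
    "extract_plane",
]

ATTACHMENTS_DIR = "attachments"
IMAGE_EXTENSIONS = (".tif", ".tiff")


def _label_dtype(data: np.ndarray) -> np.dtype:
    """Smallest unsigned integer dtype that holds every label id."""
    top = int(data.max()) if data.size else 0
    for dt in (np.uint8, np.uint16, np.uint32, np.uint64):
        if top <= np.iinfo(dt).max:
            return np.dtype(dt)
    raise StoreError("label ids exceed uint64 range")  # pragma: no cover


def write_grid(path: str | Path, img: VoxelGrid | MultiDimImage) -> Path:
    """Write a grid or multi-dimensional image as TIFF with calibration metadata."""
    path = Path(path)
    cal = img.calibration
    if isinstance(img, MultiDimImage):
        data, axes, kind = img.data, "TCZYX", img.kind
    else:
        data, axes, kind = img.data, "ZYX", img.kind
    if kind == "label":
        data = data.astype(_label_dtype(data))
    elif kind == "binary":
        data = data.astype(np.uint8)
    metadata = {
        "axes": axes,
        "kind": kind,
        "pixel_size_xy": cal.pixel_size_xy,
        "pixel_size_z": cal.pixel_size_z,
        "unit": cal.unit,
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, data, metadata=metadata, photometric="minisblack")
    return path


def _read_tiff(path: Path) -> tuple[np.ndarray, dict]:
    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta = dict(tf.shaped_metadata[0]) if tf.shaped_metadata else {}
    except (OSError, ValueError, IndexError) as exc:
        raise StoreError(f"cannot read TIFF {path}: {exc}") from exc
    return data, meta


def _calibration_from(meta: dict) -> Calibration:
    if "pixel_size_xy" in meta:
        return Calibration(
            float(meta["pixel_size_xy"]),
            float(meta.get("pixel_size_z", 1.0)),
            str(meta.get("unit", "pixel")),
        )
    return Calibration()


def _restore_kind(data: np.ndarray, kind: str) -> np.ndarray:
    if kind == "binary":
        return data.astype(bool)
    return data


def read_multidim(path: str | Path) -> MultiDimImage:
    """Read a TIFF as a (t, c, z, y, x) image, promoting missing axes to extent 1."""
    path = Path(path)
    if not path.exists():
        raise StoreError(f"image file not found: {path}")
    data, meta = _read_tiff(path)
    kind = meta.get("kind", "intensity")
    data = _restore_kind(data, kind)
    axes = meta.get("axes")
    if axes is None:
        # no metadata: infer the conventional axis order from dimensionality
        axes = "TCZYX"[5 - data.ndim :] if data.ndim <= 5 else None
        if axes is None:
            raise StoreError(f"cannot interpret {data.ndim}-dimensional TIFF {path}")
    order = "TCZYX"
    if not all(a in order for a in axes):
        raise StoreError(f"unsupported TIFF axes {axes!r} in {path}")
    # expand any missing axes and sort into (t, c, z, y, x)
    for a in order:
        if a not in axes:
            data = data[np.newaxis, ...]
            axes = a + axes
    data = np.transpose(data, [axes.index(a) for a in order])
    return MultiDimImage(data, _calibration_from(meta), kind=kind)


def read_grid(path: str | Path) -> VoxelGrid:
    """Read a TIFF expected to hold a single mono-channel stack."""
    img = read_multidim(path)
    if img.n_frames != 1 or img.n_channels != 1:
        raise StoreError(
            f"{path} holds {img.n_frames} frame(s) x {img.n_channels} channel(s); "
            "expected a single mono-channel stack"
        )
    return extract_plane(img, 1, 1)


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a results table as CSV (comma separator, header row, '.' decimal)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a results-table CSV, raising :class:`StoreError` on malformed input."""
    path = Path(path)
    if not path.exists():
        raise StoreError(f"table file not found: {path}")
    try:
        return pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise StoreError(f"malformed CSV {path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise StoreError(f"empty CSV {path}: {exc}") from exc


class ImageDatabase:
    """Handle on a local folder database."""

    def __init__(self, root: str | Path, create: bool = True):
        self.root = Path(root)
        if create:
            try:
                self.root.mkdir(parents=True, exist_ok=True)
            except OSError as exc:
                raise StoreError(f"cannot create database root {self.root}: {exc}")
        if not self.root.is_dir():
            raise StoreError(f"database root is not a directory: {self.root}")

    # -- layout ----------------------------------------------------------

    def _dataset_dir(self, project: str, dataset: str, create: bool = False) -> Path:
        if dataset == ATTACHMENTS_DIR:
            raise StoreError(
                f"{ATTACHMENTS_DIR!r} is a reserved folder name and cannot be a dataset"
            )
        path = self.root / project / dataset
        if create:
            path.mkdir(parents=True, exist_ok=True)
        return path

    def attachments_dir(self, ref: ImageRef, create: bool = False) -> Path:
        path = self._dataset_dir(ref.project, ref.dataset) / ATTACHMENTS_DIR
        if create:
            path.mkdir(parents=True, exist_ok=True)
        return path

    def resolve(self, ref: ImageRef) -> Path | None:
        """Path of the stored image file for ``ref``, or None if absent."""
        folder = self._dataset_dir(ref.project, ref.dataset)
        for ext in IMAGE_EXTENSIONS:
            candidate = folder / (ref.image + ext)
            if candidate.exists():
                return candidate
        return None

    # -- listing ---------------------------------------------------------

    def list_images(
        self, project: str | None = None, dataset: str | None = None
    ) -> list[ImageRef]:
        """All image refs, lexicographically sorted; filters narrow the scan.

        A filter naming an absent project or dataset yields an empty list.
        """
        refs: list[ImageRef] = []
        projects = (
            [self.root / project] if project is not None else sorted(self.root.iterdir())
        )
        for pdir in projects:
            if not pdir.is_dir():
                continue
            datasets = (
                [pdir / dataset] if dataset is not None else sorted(pdir.iterdir())
            )
            for ddir in datasets:
                if not ddir.is_dir() or ddir.name == ATTACHMENTS_DIR:
                    continue
                for f in sorted(ddir.iterdir()):
                    if f.is_file() and f.suffix.lower() in IMAGE_EXTENSIONS:
                        refs.append(ImageRef(pdir.name, ddir.name, f.stem))
        return sorted(refs)

    def list_attachments(self, ref: ImageRef) -> list[Path]:
        """Attachment files linked to ``ref`` by the ``<image>-`` name prefix."""
        folder = self.attachments_dir(ref)
        if not folder.is_dir():
            return []
        return sorted(
            f for f in folder.iterdir() if f.is_file() and f.name.startswith(ref.image + "-")
        )

    # -- image I/O -------------------------------------------------------

    def read_image(self, ref: ImageRef) -> MultiDimImage:
        path = self.resolve(ref)
        if path is None:
            raise StoreError(f"image not found in database: {ref}")
        return read_multidim(path)

    def write_image(self, ref: ImageRef, img: VoxelGrid | MultiDimImage) -> Path:
        """Store an image under ``ref``; an existing file is overwritten silently
        so that batch reruns are idempotent."""
        folder = self._dataset_dir(ref.project, ref.dataset, create=True)
        existing = self.resolve(ref)
        path = existing if existing is not None else folder / (ref.image + ".tif")
        return write_grid(path, img)

    # -- attachments -----------------------------------------------------

    def attach_file(self, ref: ImageRef, path: str | Path) -> Path:
        """Copy a results file into the dataset attachments folder (overwrite)."""
        src = Path(path)
        if not src.is_file():
            raise StoreError(f"attachment source not found: {src}")
        target = self.attachments_dir(ref, create=True) / src.name
        shutil.copyfile(src, target)
        return target


def init_db(root: str | Path) -> ImageDatabase:
    """Create (if needed) and open a local folder database."""
    return ImageDatabase(root, create=True)
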