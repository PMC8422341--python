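"""Synthetic 3D two-channel microscopy scenes with ground truth.

The generator rasterizes non-overlapping ellipsoidal "nuclei" into a
two-channel 8-bit stack: channel 1 is the segmentation channel (bright
objects on a dark background, well separated for a global threshold),
channel 2 carries a known per-object mean intensity for quantification.
Additive Gaussian noise is applied to both channels before rounding to
8 bits.  A fixed seed yields byte-identical stacks, and every object's
centroid, semi-axes, rasterized voxel count and true channel-2 mean are
returned as ground truth, so end-to-end pipeline results can be checked
against construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import Calibration, ImageRef, MultiDimImage
from .errors import FixtureError
from .store import ImageDatabase, write_table

__all__ = ["SceneSpec", "generate_scene", "populate_db"]

GROUND_TRUTH_SUFFIX = "-ground-truth.csv"


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    Defaults describe a scene that a classical filter/threshold/label
    pipeline segments cleanly: bright (120) ellipsoids on a dark (20)
    background with mild Gaussian noise (sd 5), objects large enough
    (semi-axes >= 10 voxels in XY, >= 5 in Z) that their rasterized and
    median-filtered volumes stay close to the analytic ellipsoid volume.
    One object is forced to touch an X/Y border so edge-exclusion paths are
    exercised.
    """

    shape: tuple[int, int, int] = (32, 192, 192)  # (nz, ny, nx)
    calibration: Calibration = field(default_factory=lambda: Calibration(0.2, 1.0, "micron"))
    n_objects: int = 6
    radius_xy: tuple[int, int] = (10, 14)  # inclusive range, voxels
    radius_z: tuple[int, int] = (5, 8)
    edge_touching: int = 1
    background: float = 20.0
    object_mean: float = 120.0
    signal_background: float = 30.0
    signal_range: tuple[float, float] = (80.0, 200.0)
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.edge_touching > self.n_objects:
            raise FixtureError("edge_touching cannot exceed n_objects")


def _ellipsoid_voxels(shape, center, semi):
    zz, yy, xx = np.indices(shape)
    cz, cy, cx = center
    rz, ry, rx = semi
    return ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _boxes_overlap(a, b, margin=2):
    return all(a[i][0] - margin < b[i][1] and b[i][0] - margin < a[i][1] for i in range(3))


def generate_scene(spec: SceneSpec) -> tuple[MultiDimImage, pd.DataFrame]:
    """Rasterize a scene, returning the (1, 2, z, y, x) image and ground truth.

    Ground truth has one row per object: voxel-space centroid, semi-axes,
    rasterized voxel count, true channel-2 mean and an edge flag.  Raises
    :class:`FixtureError` when the requested objects cannot be placed without
    overlap within the retry budget.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape

    def _between(lo, hi):
        if lo >= hi:
            raise FixtureError(
                f"grid extents {spec.shape} are too small for the requested "
                "object radii; reduce n_objects or the radius ranges"
            )
        return int(rng.integers(lo, hi))
    placed: list[tuple] = []  # (center, semi, bbox, touches_edge)
    for index in range(spec.n_objects):
        on_edge = index < spec.edge_touching
        for _ in range(1000):
            rz = int(rng.integers(spec.radius_z[0], spec.radius_z[1] + 1))
            ry = int(rng.integers(spec.radius_xy[0], spec.radius_xy[1] + 1))
            rx = int(rng.integers(spec.radius_xy[0], spec.radius_xy[1] + 1))
            cz = _between(rz + 2, nz - rz - 2)
            if on_edge:
                # center close to the x=0 plane so the object crosses it
                cx = _between(2, max(3, rx - 1))
                cy = _between(ry + 2, ny - ry - 2)
            else:
                cy = _between(ry + 2, ny - ry - 2)
                cx = _between(rx + 2, nx - rx - 2)
            bbox = ((cz - rz, cz + rz), (cy - ry, cy + ry), (cx - rx, cx + rx))
            if all(not _boxes_overlap(bbox, other[2]) for other in placed):
                placed.append(((cz, cy, cx), (rz, ry, rx), bbox, on_edge))
                break
        else:
            raise FixtureError(
                f"could not place object {index + 1}/{spec.n_objects} without "
                "overlap; reduce n_objects or the radius ranges"
            )

    ch1 = np.full(spec.shape, spec.background, dtype=np.float64)
    ch2 = np.full(spec.shape, spec.signal_background, dtype=np.float64)
    records = []
    for obj_id, (center, semi, _, on_edge) in enumerate(placed, start=1):
        mask = _ellipsoid_voxels(spec.shape, center, semi)
        signal_mean = float(np.round(rng.uniform(*spec.signal_range)))
        ch1[mask] = spec.object_mean
        ch2[mask] = signal_mean
        records.append(
            {
                "object": obj_id,
                "cz": center[0],
                "cy": center[1],
                "cx": center[2],
                "rz": semi[0],
                "ry": semi[1],
                "rx": semi[2],
                "voxels": int(mask.sum()),
                "signal_mean": signal_mean,
                "touches_edge": int(on_edge),
            }
        )

    stack = np.stack([ch1, ch2])  # (c, z, y, x)
    stack = stack + rng.normal(0.0, spec.noise_sd, stack.shape)
    stack = np.clip(np.rint(stack), 0, 255).astype(np.uint8)
    img = MultiDimImage(stack[np.newaxis, ...], spec.calibration)
    return img, pd.DataFrame.from_records(records)


def populate_db(
    db: ImageDatabase,
    n_images: int = 3,
    spec: SceneSpec | None = None,
    seed: int = 0,
    project: str = "demo",
    dataset: str = "stacks",
) -> list[ImageRef]:
    """Write ``n_images`` generated scenes into the database.

    Images are named ``img001..``; each scene's ground truth is stored as a
    CSV attachment named ``<image>-ground-truth.csv``.  The per-image seed is
    derived from ``seed`` so re-populating with the same seed reproduces the
    database byte for byte.
    """
    import tempfile
    from pathlib import Path

    spec = spec or SceneSpec()
    refs = []
    for i in range(1, n_images + 1):
        per_image = SceneSpec(**{**spec.__dict__, "seed": (seed * 1000 + i) % (2**31)})
        img, truth = generate_scene(per_image)
        ref = ImageRef(project, dataset, f"img{i:03d}")
        db.write_image(ref, img)
        with tempfile.TemporaryDirectory() as tmp:
            path = Path(tmp) / f"{ref.image}{GROUND_TRUTH_SUFFIX}"
            write_table(truth, path)
            db.attach_file(ref, path)
        refs.append(ref)
    return refs


def read_ground_truth(db: ImageDatabase, ref: ImageRef) -> pd.DataFrame:
    """Load the ground-truth attachment written by :func:`populate_db`."""
    from .store import read_table

    path = db.attachments_dir(ref) / f"{ref.image}{GROUND_TRUTH_SUFFIX}"
    return read_table(path)
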