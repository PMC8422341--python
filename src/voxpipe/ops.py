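"""The core module catalog.

Every operation has the same shape: it receives the engine's execution state
(current image, provenance, keyword context, database handle) plus a fully
resolved, keyword-substituted ``str -> str`` parameter map, and returns the
image that becomes current.  Table-producing analysis modules write CSV side
effects and hand the current image back untouched.

Conventions used throughout the catalog:

* foreground is strictly ``value > threshold``;
* object connectivity is 26 in 3D (8 for single-slice stacks); hole filling
  floods the background with 6-connectivity;
* labels are consecutive ``1..N`` in raster order of each object's first
  voxel, re-established after every label-producing or label-filtering step;
* sizes (``minSize``/``maxSize``) are voxel counts; geometric measurements
  are calibrated.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import BinaryMask, Calibration, ImageRef, LabelMap, VoxelGrid
from .engine import module
from .errors import ModuleError, StoreError
from .store import read_grid, read_table, write_grid, write_table

IO = "Input/Output"
CAL = "Calibration"
PROC = "Processing"
FILT = "Filtering"
THRESH = "Thresholding"
LABEL = "Labelling"
POST = "Post-processing"
ANA = "Analysis"
TAB = "Measurements processing"


# --------------------------------------------------------------------------
# parameter parsing helpers
# --------------------------------------------------------------------------


def _float(params: dict, name: str, mod: str) -> float:
    raw = params[name]
    try:
        return float(raw)
    except ValueError:
        raise ModuleError(f"{mod}: parameter {name!r} must be numeric, got {raw!r}")


def _int(params: dict, name: str, mod: str) -> int:
    raw = params[name]
    try:
        return int(raw)
    except ValueError:
        raise ModuleError(f"{mod}: parameter {name!r} must be an integer, got {raw!r}")


def _yesno(params: dict, name: str, mod: str) -> bool:
    raw = params[name].strip().casefold()
    if raw in {"yes", "true", "1"}:
        return True
    if raw in {"no", "false", "0"}:
        return False
    raise ModuleError(f"{mod}: parameter {name!r} must be yes/no, got {params[name]!r}")


def _split_list(raw: str) -> list[str]:
    return [item.strip() for item in raw.split(",") if item.strip()]


def _find_file(directory: str, name: str, mod: str) -> Path:
    """Resolve a referenced file, trying the bare name then TIFF extensions."""
    base = Path(directory)
    for candidate in (base / name, base / (name + ".tif"), base / (name + ".tiff")):
        if candidate.is_file():
            return candidate
    raise ModuleError(
        f"{mod}: file {name!r} not found in {directory!r} "
        "(auxiliary images must be saved locally first)"
    )


def _out_image_path(directory: str, name: str) -> Path:
    path = Path(directory) / name
    if path.suffix.lower() not in (".tif", ".tiff"):
        path = path.with_name(path.name + ".tif")
    return path


def _require_label(state, mod: str) -> LabelMap:
    if not isinstance(state.current, LabelMap):
        raise ModuleError(f"{mod}: current image must be a label map")
    return state.current


def _as_mask(grid: VoxelGrid) -> np.ndarray:
    """Boolean foreground view of a mask, label map or grayscale grid (> 0)."""
    if grid.data.dtype == bool:
        return grid.data
    return grid.data > 0


def _structure(nz: int) -> np.ndarray:
    """Full connectivity: 26 in 3D; on a single-slice stack this restricts
    itself to 8-connectivity in the plane."""
    return np.ones((3, 3, 3), dtype=bool)


def _relabel_sequential(labels: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Map the kept original ids (ascending) onto 1..N, everything else to 0.

    scipy assigns component ids in raster order of first-encountered voxel,
    so renumbering kept ids in ascending order preserves raster order.
    """
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[np.asarray(sorted(int(k) for k in keep), dtype=np.int64)] = np.arange(
        1, len(keep) + 1, dtype=np.int32
    )
    return lut[labels]


def _ellipsoid_footprint(radius_xy: int, radius_z: int) -> np.ndarray:
    """Ellipsoidal neighborhood with semi-axes (radius_xy, radius_xy, radius_z)."""
    rz, ry, rx = radius_z, radius_xy, radius_xy
    zz, yy, xx = np.indices((2 * rz + 1, 2 * ry + 1, 2 * rx + 1))
    out = (
        ((zz - rz) / max(rz, 1e-9)) ** 2
        + ((yy - ry) / max(ry, 1e-9)) ** 2
        + ((xx - rx) / max(rx, 1e-9)) ** 2
    ) <= 1.0
    out[rz, ry, rx] = True
    return out


# --------------------------------------------------------------------------
# Input/Output
# --------------------------------------------------------------------------


@module(
    "input",
    IO,
    "Load one channel/frame of a database image as the current image",
    params=(
        ("project", "?project?", "project of the image to load"),
        ("dataset", "?dataset?", "dataset of the image to load"),
        ("image", "?image?", "image name (no extension)"),
        ("channel", "1", "1-based channel"),
        ("frame", "1", "1-based frame"),
    ),
    needs_image=False,
)
def op_input(state, params):
    from .containers import extract_plane

    ref = ImageRef(params["project"], params["dataset"], params["image"])
    channel = _int(params, "channel", "input")
    frame = _int(params, "frame", "input")
    img = state.db.read_image(ref)
    try:
        grid = extract_plane(img, channel, frame)
    except StoreError as exc:
        raise ModuleError(f"input: {exc}")
    state.info.channel = channel
    state.info.frame = frame
    return grid


@module(
    "save",
    IO,
    "Save the current image as TIFF into a work folder",
    params=(
        ("dir", None, "target directory (keywords allowed)"),
        ("file", None, "file name; .tif appended when no extension"),
    ),
)
def op_save(state, params):
    path = _out_image_path(params["dir"], params["file"])
    write_grid(path, state.current)
    return state.current


@module(
    "output",
    IO,
    "Store the current image into the database",
    params=(
        ("image", None, "image name to store under"),
        ("dataset", "?dataset?", "target dataset"),
        ("project", "?project?", "target project"),
    ),
)
def op_output(state, params):
    ref = ImageRef(params["project"], params["dataset"], params["image"])
    state.db.write_image(ref, state.current)
    return state.current


@module(
    "attach",
    IO,
    "Attach a local results file to the original database image",
    params=(
        ("dir", None, "directory of the file"),
        ("file", None, "file name"),
    ),
    needs_image=False,
)
def op_attach(state, params):
    src = Path(params["dir"]) / params["file"]
    if not src.is_file():
        raise ModuleError(f"attach: file not found: {src}")
    state.db.attach_file(state.info.ref, src)
    return state.current


@module(
    "deleteList",
    IO,
    "Delete a comma-separated list of work files",
    params=(
        ("dir", None, "directory holding the files"),
        ("list", None, "comma-separated file names"),
    ),
    needs_image=False,
)
def op_deleteList(state, params):
    base = Path(params["dir"])
    for name in _split_list(params["list"]):
        candidates = [base / name, base / (name + ".tif"), base / (name + ".tiff")]
        hit = next((c for c in candidates if c.is_file()), None)
        if hit is None:
            state.warn(f"deleteList: {name!r} not found in {base}")
        else:
            hit.unlink()
    return state.current


# --------------------------------------------------------------------------
# Calibration
# --------------------------------------------------------------------------


@module(
    "calibration",
    CAL,
    "Apply a spatial calibration to the current image",
    params=(
        ("xy", None, "pixel size in X and Y"),
        ("z", None, "slice spacing"),
        ("unit", "pixel", "unit name"),
    ),
)
def op_calibration(state, params):
    xy = _float(params, "xy", "calibration")
    z = _float(params, "z", "calibration")
    if xy <= 0 or z <= 0:
        raise ModuleError("calibration: sizes must be > 0")
    return state.current.with_calibration(Calibration(xy, z, params["unit"]))


@module(
    "saveCalibration",
    CAL,
    "Save the current calibration to a small text file",
    params=(("dir", None, "target directory"), ("file", None, "file name")),
)
def op_saveCalibration(state, params):
    cal = state.current.calibration
    path = Path(params["dir"]) / params["file"]
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(f"xy: {cal.pixel_size_xy!r}\nz: {cal.pixel_size_z!r}\nunit: {cal.unit}\n")
    return state.current


@module(
    "loadCalibration",
    CAL,
    "Load a calibration text file and apply it to the current image",
    params=(("dir", None, "directory of the file"), ("file", None, "file name")),
)
def op_loadCalibration(state, params):
    path = Path(params["dir"]) / params["file"]
    if not path.is_file():
        raise ModuleError(f"loadCalibration: file not found: {path}")
    values = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        key, sep, value = line.partition(":")
        if not sep:
            raise ModuleError(f"loadCalibration: line {lineno}: expected 'key: value'")
        values[key.strip()] = value.strip()
    try:
        cal = Calibration(float(values["xy"]), float(values["z"]), values.get("unit", "pixel"))
    except (KeyError, ValueError) as exc:
        raise ModuleError(f"loadCalibration: bad calibration file {path}: {exc}")
    return state.current.with_calibration(cal)


# --------------------------------------------------------------------------
# Processing
# --------------------------------------------------------------------------


@module(
    "crop",
    PROC,
    "Crop the current image to a 0-based half-open box",
    params=(
        ("xmin", "0", "first X voxel"),
        ("xmax", "max", "one past last X voxel, or 'max'"),
        ("ymin", "0", "first Y voxel"),
        ("ymax", "max", "one past last Y voxel, or 'max'"),
        ("zmin", "0", "first Z slice"),
        ("zmax", "max", "one past last Z slice, or 'max'"),
    ),
)
def op_crop(state, params):
    grid = state.current
    nz, ny, nx = grid.shape
    bounds = {}
    for name, extent in (("x", nx), ("y", ny), ("z", nz)):
        lo = _int(params, name + "min", "crop")
        hi_raw = params[name + "max"].strip()
        hi = extent if hi_raw.casefold() == "max" else _int(params, name + "max", "crop")
        if not (0 <= lo < hi <= extent):
            raise ModuleError(
                f"crop: invalid {name} bounds [{lo}, {hi}) for extent {extent}"
            )
        bounds[name] = (lo, hi)
    (x0, x1), (y0, y1), (z0, z1) = bounds["x"], bounds["y"], bounds["z"]
    return grid.with_data(grid.data[z0:z1, y0:y1, x0:x1])


@module(
    "math",
    PROC,
    "Voxelwise arithmetic with a constant, clamped to the dtype range",
    params=(
        ("operation", "add", "one of add, subtract, multiply, divide"),
        ("value", None, "numeric operand"),
    ),
)
def op_math(state, params):
    grid = state.current
    value = _float(params, "value", "math")
    operation = params["operation"].strip().casefold()
    if operation not in {"add", "subtract", "multiply", "divide"}:
        raise ModuleError(
            f"math: unknown operation {params['operation']!r} "
            "(choose add, subtract, multiply, divide)"
        )
    if operation == "divide" and value == 0:
        raise ModuleError("math: division by zero")
    data = grid.data.astype(np.float64)
    data = {
        "add": data + value,
        "subtract": data - value,
        "multiply": data * value,
        "divide": data / value if value else data,
    }[operation]
    dtype = grid.data.dtype
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        data = np.clip(np.rint(data), info.min, info.max)
    return grid.with_data(data.astype(dtype))


@module(
    "scale",
    PROC,
    "Resample the image by per-axis factors, adjusting the calibration",
    params=(
        ("factorXY", None, "scale factor in X and Y (> 0)"),
        ("factorZ", "1", "scale factor in Z (> 0)"),
    ),
)
def op_scale(state, params):
    grid = state.current
    fxy = _float(params, "factorXY", "scale")
    fz = _float(params, "factorZ", "scale")
    if fxy <= 0 or fz <= 0:
        raise ModuleError("scale: factors must be > 0")
    order = 0 if grid.kind in ("label", "binary") else 1
    data = grid.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    zoomed = ndimage.zoom(data, (fz, fxy, fxy), order=order, mode="nearest")
    if grid.data.dtype == bool:
        zoomed = zoomed.astype(bool)
    cal = grid.calibration
    new_cal = Calibration(cal.pixel_size_xy / fxy, cal.pixel_size_z / fz, cal.unit)
    return type(grid)(zoomed.astype(grid.data.dtype), new_cal)


# --------------------------------------------------------------------------
# Filtering
# --------------------------------------------------------------------------


@module(
    "filters",
    FILT,
    "3D neighborhood filter with an ellipsoidal kernel",
    params=(
        ("filter", "median", "one of median, mean, min, max, gauss"),
        ("radiusXY", "2", "semi-axis in X and Y (voxels); gauss sigma"),
        ("radiusZ", "2", "semi-axis in Z (voxels); gauss sigma"),
    ),
)
def op_filters(state, params):
    grid = state.current
    name = params["filter"].strip().casefold()
    rxy = _float(params, "radiusXY", "filters")
    rz = _float(params, "radiusZ", "filters")
    if rxy < 0 or rz < 0:
        raise ModuleError("filters: radii must be >= 0")
    if name == "gauss":
        data = ndimage.gaussian_filter(
            grid.data.astype(np.float64), sigma=(rz, rxy, rxy), mode="nearest"
        )
        if np.issubdtype(grid.data.dtype, np.integer):
            info = np.iinfo(grid.data.dtype)
            data = np.clip(np.rint(data), info.min, info.max)
        return grid.with_data(data.astype(grid.data.dtype))
    filters = {
        "median": ndimage.median_filter,
        "mean": None,
        "min": ndimage.minimum_filter,
        "max": ndimage.maximum_filter,
    }
    if name not in filters:
        raise ModuleError(
            f"filters: unknown filter {params['filter']!r} "
            "(choose median, mean, min, max, gauss)"
        )
    footprint = _ellipsoid_footprint(int(round(rxy)), int(round(rz)))
    if name == "mean":
        weights = footprint / footprint.sum()
        data = ndimage.correlate(
            grid.data.astype(np.float64), weights, mode="nearest"
        )
        if np.issubdtype(grid.data.dtype, np.integer):
            info = np.iinfo(grid.data.dtype)
            data = np.clip(np.rint(data), info.min, info.max)
        return grid.with_data(data.astype(grid.data.dtype))
    data = filters[name](grid.data, footprint=footprint, mode="nearest")
    return grid.with_data(data)


# --------------------------------------------------------------------------
# Thresholding
# --------------------------------------------------------------------------


def _check_nondegenerate(values: np.ndarray, mod: str) -> None:
    if values.min() == values.max():
        raise ModuleError(f"{mod}: degenerate histogram (constant image)")


def otsu_threshold(values: np.ndarray) -> float:
    """Threshold maximizing the between-class variance over the value histogram.

    Candidates are the distinct values; foreground is strictly ``> T``.  Ties
    resolve to the smallest candidate.
    """
    vals, counts = np.unique(values.ravel(), return_counts=True)
    if len(vals) < 2:
        raise ModuleError("autoThreshold: degenerate histogram (constant image)")
    vals_f = vals.astype(np.float64)
    w0 = np.cumsum(counts)[:-1]
    w1 = values.size - w0
    s0 = np.cumsum(counts * vals_f)[:-1]
    mu0 = s0 / w0
    mu1 = (counts @ vals_f - s0) / w1
    between = w0 * w1 * (mu0 - mu1) ** 2
    return float(vals_f[int(np.argmax(between))])


def isodata_threshold(values: np.ndarray) -> float:
    """Fixpoint of T = (mean below + mean above) / 2, seeded at the global mean."""
    flat = values.astype(np.float64).ravel()
    t = flat.mean()
    for _ in range(500):
        below = flat[flat <= t]
        above = flat[flat > t]
        if below.size == 0 or above.size == 0:
            break
        t_new = (below.mean() + above.mean()) / 2.0
        if abs(t_new - t) < 1e-9:
            t = t_new
            break
        t = t_new
    return float(t)


@module(
    "autoThreshold",
    THRESH,
    "Automatic global threshold from the full 3D histogram",
    params=(("method", "Otsu", "one of Otsu, Mean, IsoData"),),
)
def op_autoThreshold(state, params):
    grid = state.current
    method = params["method"].strip().casefold()
    _check_nondegenerate(grid.data, "autoThreshold")
    if method == "otsu":
        t = otsu_threshold(grid.data)
    elif method == "mean":
        t = float(grid.data.mean())
    elif method == "isodata":
        t = isodata_threshold(grid.data)
    else:
        raise ModuleError(
            f"autoThreshold: unknown method {params['method']!r} "
            "(choose Otsu, Mean, IsoData)"
        )
    state.log(f"autoThreshold: method={params['method']} threshold={t:g}")
    return BinaryMask(grid.data > t, grid.calibration)


@module(
    "threshold",
    THRESH,
    "Fixed global threshold; foreground is strictly above it",
    params=(("low", None, "threshold value"),),
)
def op_threshold(state, params):
    grid = state.current
    low = _float(params, "low", "threshold")
    return BinaryMask(grid.data > low, grid.calibration)


@module(
    "percentile",
    THRESH,
    "Threshold so that at most the given percentage of voxels is foreground",
    params=(("percentile", None, "percentage of voxels above the threshold, in (0, 100)"),),
)
def op_percentile(state, params):
    grid = state.current
    pct = _float(params, "percentile", "percentile")
    if not 0 < pct < 100:
        raise ModuleError(f"percentile: value must be in (0, 100), got {pct}")
    values = np.sort(grid.data.ravel())
    budget = int(math.floor(grid.data.size * pct / 100.0))
    # smallest T (among distinct values) with at most `budget` voxels above it
    t = values[-budget - 1] if budget < values.size else values[0]
    while (grid.data > t).sum() > budget:  # step up through ties
        higher = values[values > t]
        t = higher[0]
    state.log(f"percentile: threshold={t:g}")
    return BinaryMask(grid.data > t, grid.calibration)


@module(
    "hysteresis",
    THRESH,
    "Two-level threshold: weak voxels survive only when 26-connected to a strong one",
    params=(
        ("high", None, "strong (seed) threshold"),
        ("low", None, "weak threshold (<= high)"),
    ),
)
def op_hysteresis(state, params):
    grid = state.current
    high = _float(params, "high", "hysteresis")
    low = _float(params, "low", "hysteresis")
    if low > high:
        raise ModuleError(f"hysteresis: low ({low}) must be <= high ({high})")
    weak = grid.data > low
    strong = grid.data > high
    labels, _ = ndimage.label(weak, structure=_structure(grid.shape[0]))
    seeds = np.unique(labels[strong])
    seeds = seeds[seeds > 0]
    mask = np.isin(labels, seeds)
    return BinaryMask(mask, grid.calibration)


# --------------------------------------------------------------------------
# Labelling
# --------------------------------------------------------------------------


@module(
    "label",
    LABEL,
    "26-connected component labelling with voxel-count size filtering",
    params=(
        ("minSize", "0", "minimum object size in voxels"),
        ("maxSize", "inf", "maximum object size in voxels"),
    ),
)
def op_label(state, params):
    grid = state.current
    min_size = _float(params, "minSize", "label")
    max_size = _float(params, "maxSize", "label")
    mask = _as_mask(grid)
    labels, n = ndimage.label(mask, structure=_structure(grid.shape[0]))
    if n == 0:
        state.warn("label: empty mask, no objects found")
        return LabelMap(labels.astype(np.int32), grid.calibration)
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    ids = np.arange(1, n + 1)
    keep = ids[(counts[1:] >= min_size) & (counts[1:] <= max_size)]
    return LabelMap(_relabel_sequential(labels, keep), grid.calibration)


# --------------------------------------------------------------------------
# Post-processing
# --------------------------------------------------------------------------


@module(
    "fillHoles",
    POST,
    "Fill background cavities that are not 6-connected to the image border",
)
def op_fillHoles(state, params):
    grid = state.current
    if isinstance(grid, LabelMap):
        out = grid.data.copy()
        objects = ndimage.find_objects(grid.data)
        for idx, sl in enumerate(objects, start=1):
            if sl is None:
                continue
            region = grid.data[sl] == idx
            filled = _fill_holes(region)
            out[sl][filled & ~region] = idx
        return LabelMap(out, grid.calibration)
    return BinaryMask(_fill_holes(_as_mask(grid)), grid.calibration)


def _fill_holes(mask: np.ndarray) -> np.ndarray:
    # single-slice stacks are filled in-plane; a 3D fill would treat every
    # in-plane cavity as open towards the missing z-neighbors
    if mask.shape[0] == 1:
        return ndimage.binary_fill_holes(mask[0])[np.newaxis]
    return ndimage.binary_fill_holes(mask)


@module(
    "closing",
    POST,
    "Morphological closing (dilation then erosion) with an ellipsoidal element",
    params=(
        ("radiusXY", "2", "element semi-axis in X and Y (voxels)"),
        ("radiusZ", "2", "element semi-axis in Z (voxels)"),
    ),
)
def op_closing(state, params):
    grid = state.current
    rxy = _int(params, "radiusXY", "closing")
    rz = _int(params, "radiusZ", "closing")
    if rxy < 0 or rz < 0:
        raise ModuleError("closing: radii must be >= 0")
    footprint = _ellipsoid_footprint(rxy, rz)
    mask = _as_mask(grid)
    closed = ndimage.binary_erosion(
        ndimage.binary_dilation(mask, structure=footprint),
        structure=footprint,
        border_value=1,
    )
    return BinaryMask(closed, grid.calibration)


def _labelled_input(state, mod: str) -> LabelMap:
    """Accept a label map directly, or label a binary mask on the fly."""
    grid = state.current
    if isinstance(grid, LabelMap):
        return grid
    mask = _as_mask(grid)
    labels, _ = ndimage.label(mask, structure=_structure(grid.shape[0]))
    return LabelMap(labels.astype(np.int32), grid.calibration)


@module(
    "excludeEdges",
    POST,
    "Remove objects touching the X/Y image borders (and Z borders on request)",
    params=(
        ("edgeXY", "yes", "remove objects touching any X or Y border plane"),
        ("edgeZ", "no", "also remove objects touching the Z border planes"),
    ),
)
def op_excludeEdges(state, params):
    lab = _labelled_input(state, "excludeEdges")
    edge_xy = _yesno(params, "edgeXY", "excludeEdges")
    edge_z = _yesno(params, "edgeZ", "excludeEdges")
    data = lab.data
    touching: set[int] = set()
    if edge_xy:
        for plane in (data[:, 0, :], data[:, -1, :], data[:, :, 0], data[:, :, -1]):
            touching.update(np.unique(plane).tolist())
    if edge_z:
        for plane in (data[0], data[-1]):
            touching.update(np.unique(plane).tolist())
    touching.discard(0)
    keep = np.array([i for i in np.unique(data) if i > 0 and i not in touching])
    return LabelMap(_relabel_sequential(data, keep), lab.calibration)


@module("keepBiggest", POST, "Keep only the largest object (smallest id wins ties)")
def op_keepBiggest(state, params):
    lab = _labelled_input(state, "keepBiggest")
    n = lab.n_labels
    if n == 0:
        state.warn("keepBiggest: empty label map")
        return lab
    counts = np.bincount(lab.data.ravel(), minlength=n + 1)
    counts[0] = -1
    biggest = int(np.argmax(counts))  # argmax returns the first (smallest) id on ties
    return LabelMap(_relabel_sequential(lab.data, np.array([biggest])), lab.calibration)


@module(
    "filterSize",
    POST,
    "Keep objects whose voxel count lies in [minSize, maxSize]",
    params=(
        ("minSize", "0", "minimum object size in voxels"),
        ("maxSize", "inf", "maximum object size in voxels"),
    ),
)
def op_filterSize(state, params):
    lab = _labelled_input(state, "filterSize")
    min_size = _float(params, "minSize", "filterSize")
    max_size = _float(params, "maxSize", "filterSize")
    counts = np.bincount(lab.data.ravel(), minlength=lab.n_labels + 1)
    ids = np.arange(1, lab.n_labels + 1)
    keep = ids[(counts[1:] >= min_size) & (counts[1:] <= max_size)]
    return LabelMap(_relabel_sequential(lab.data, keep), lab.calibration)


@module(
    "filterShape",
    POST,
    "Keep objects whose shape measure lies in [min, max]",
    params=(
        ("measure", "compactness", "one of compactness, sphericity, volume, voxels, surface"),
        ("min", "0", "lower bound (inclusive)"),
        ("max", "inf", "upper bound (inclusive)"),
    ),
)
def op_filterShape(state, params):
    lab = _labelled_input(state, "filterShape")
    measure = params["measure"].strip().casefold()
    lo = _float(params, "min", "filterShape")
    hi = _float(params, "max", "filterShape")
    table = measure_labels(lab, ["voxels", "volume", "surface", "compactness", "sphericity"])
    if measure not in table.columns:
        raise ModuleError(
            f"filterShape: unknown measure {params['measure']!r} "
            "(choose compactness, sphericity, volume, voxels, surface)"
        )
    values = table[measure].to_numpy()
    keep = table["label"].to_numpy()[(values >= lo) & (values <= hi)]
    return LabelMap(_relabel_sequential(lab.data, keep), lab.calibration)


# --------------------------------------------------------------------------
# Analysis
# --------------------------------------------------------------------------

GEOMETRY_MEASURES = ("voxels", "volume", "surface", "compactness", "sphericity", "centroid", "bbox")
INTENSITY_MEASURES = ("mean", "sum", "sd", "min", "max", "median")


def surface_areas(lab: LabelMap) -> np.ndarray:
    """Calibrated surface per label by counting exposed voxel faces.

    A face is exposed when the 6-neighbor across it carries a different label
    (or lies outside the volume).  Index i holds the area for label i.
    """
    cal = lab.calibration
    sx = sy = cal.pixel_size_xy
    sz = cal.pixel_size_z
    n = lab.n_labels
    areas = np.zeros(n + 1, dtype=np.float64)
    padded = np.pad(lab.data, 1)
    for axis, face_area in ((0, sx * sy), (1, sx * sz), (2, sy * sz)):
        arr = np.moveaxis(padded, axis, 0)
        front, back = arr[:-1], arr[1:]
        diff = front != back
        for side in (front[diff], back[diff]):
            side = side[side > 0]
            areas += np.bincount(side, minlength=n + 1) * face_area
    return areas


def measure_labels(lab: LabelMap, measures: list[str]) -> pd.DataFrame:
    """Per-label geometry/shape table; first column is the object label."""
    unknown = [m for m in measures if m not in GEOMETRY_MEASURES]
    if unknown:
        raise ModuleError(
            f"measurement: unknown measure(s) {unknown} (choose from {list(GEOMETRY_MEASURES)})"
        )
    ids = lab.labels()
    cal = lab.calibration
    counts = np.bincount(lab.data.ravel(), minlength=lab.n_labels + 1)
    columns: dict[str, np.ndarray] = {"label": ids}
    need_surface = {"surface", "compactness", "sphericity"} & set(measures)
    surf = surface_areas(lab) if need_surface else None
    for m in measures:
        if m == "voxels":
            columns["voxels"] = counts[ids]
        elif m == "volume":
            columns["volume"] = counts[ids] * cal.voxel_volume
        elif m == "surface":
            columns["surface"] = surf[ids]
        elif m in ("compactness", "sphericity"):
            volume = counts[ids] * cal.voxel_volume
            compact = 36.0 * np.pi * volume**2 / surf[ids] ** 3
            columns[m] = compact if m == "compactness" else np.cbrt(compact)
        elif m == "centroid":
            if len(ids):
                com = np.array(ndimage.center_of_mass(np.ones_like(lab.data), lab.data, ids))
            else:
                com = np.zeros((0, 3))
            columns["cx"] = com[:, 2] * cal.pixel_size_xy
            columns["cy"] = com[:, 1] * cal.pixel_size_xy
            columns["cz"] = com[:, 0] * cal.pixel_size_z
        elif m == "bbox":
            slices = ndimage.find_objects(lab.data)
            boxes = {k: [] for k in ("bx_min", "bx_max", "by_min", "by_max", "bz_min", "bz_max")}
            for i in ids:
                sl = slices[i - 1]
                boxes["bz_min"].append(sl[0].start), boxes["bz_max"].append(sl[0].stop - 1)
                boxes["by_min"].append(sl[1].start), boxes["by_max"].append(sl[1].stop - 1)
                boxes["bx_min"].append(sl[2].start), boxes["bx_max"].append(sl[2].stop - 1)
            for k in ("bx_min", "bx_max", "by_min", "by_max", "bz_min", "bz_max"):
                columns[k] = np.asarray(boxes[k], dtype=np.int64)
    return pd.DataFrame(columns)


def quantify_labels(lab: LabelMap, raw: VoxelGrid, measures: list[str]) -> pd.DataFrame:
    """Per-label intensity statistics over the raw grid."""
    unknown = [m for m in measures if m not in INTENSITY_MEASURES]
    if unknown:
        raise ModuleError(
            f"quantification: unknown measure(s) {unknown} "
            f"(choose from {list(INTENSITY_MEASURES)})"
        )
    if raw.shape != lab.shape:
        raise ModuleError(
            f"quantification: raw grid extents {raw.shape} do not match "
            f"label map extents {lab.shape}"
        )
    ids = lab.labels()
    data = raw.data.astype(np.float64)
    columns: dict[str, np.ndarray] = {"label": ids}
    fns = {
        "mean": ndimage.mean,
        "sum": ndimage.sum_labels,
        "sd": ndimage.standard_deviation,
        "min": ndimage.minimum,
        "max": ndimage.maximum,
        "median": ndimage.median,
    }
    for m in measures:
        columns[m] = (
            np.asarray(fns[m](data, lab.data, ids), dtype=np.float64)
            if len(ids)
            else np.zeros(0)
        )
    return pd.DataFrame(columns)


def _write_analysis_table(state, table: pd.DataFrame, params, mod: str) -> None:
    path = Path(params["dir"]) / params["file"]
    if table.empty:
        state.warn(f"{mod}: empty label map, writing header-only table")
    write_table(table, path)


@module(
    "measurement",
    ANA,
    "Per-object geometry and shape measurements, written as CSV",
    params=(
        ("list", None, "comma-separated measures: voxels, volume, surface, "
                       "compactness, sphericity, centroid, bbox"),
        ("dir", None, "target directory"),
        ("file", None, "CSV file name"),
    ),
)
def op_measurement(state, params):
    lab = _require_label(state, "measurement")
    measures = _split_list(params["list"])
    table = measure_labels(lab, measures)
    _write_analysis_table(state, table, params, "measurement")
    return state.current


@module(
    "quantification",
    ANA,
    "Per-object intensity statistics over a previously saved raw image, as CSV",
    params=(
        ("dirRaw", None, "directory of the saved raw image"),
        ("fileRaw", None, "file name of the saved raw image"),
        ("list", None, "comma-separated statistics: mean, sum, sd, min, max, median"),
        ("dir", None, "target directory"),
        ("file", None, "CSV file name"),
    ),
)
def op_quantification(state, params):
    lab = _require_label(state, "quantification")
    raw_path = _find_file(params["dirRaw"], params["fileRaw"], "quantification")
    raw = read_grid(raw_path)
    table = quantify_labels(lab, raw, _split_list(params["list"]))
    _write_analysis_table(state, table, params, "quantification")
    return state.current


def _load_partner_labels(state, params, mod: str) -> LabelMap:
    path = _find_file(params["dirRaw"], params["fileRaw"], mod)
    partner = read_grid(path)
    if not isinstance(partner, LabelMap):
        if np.issubdtype(partner.data.dtype, np.integer):
            partner = LabelMap(partner.data, partner.calibration)
        else:
            raise ModuleError(f"{mod}: {path} does not hold a label map")
    if partner.shape != state.current.shape:
        raise ModuleError(
            f"{mod}: partner extents {partner.shape} do not match "
            f"current extents {state.current.shape}"
        )
    return partner


def _centroids(lab: LabelMap) -> tuple[np.ndarray, np.ndarray]:
    """(ids, voxel-space centroids (z, y, x)) for every label."""
    ids = lab.labels()
    if len(ids) == 0:
        return ids, np.zeros((0, 3))
    com = np.array(ndimage.center_of_mass(np.ones_like(lab.data), lab.data, ids))
    return ids, com


@module(
    "coloc",
    ANA,
    "Pairwise overlap between the current label map and a saved one, as CSV",
    params=(
        ("dirRaw", None, "directory of the saved partner label map"),
        ("fileRaw", None, "file name of the saved partner label map"),
        ("dir", None, "target directory"),
        ("file", None, "CSV file name"),
    ),
)
def op_coloc(state, params):
    lab = _require_label(state, "coloc")
    partner = _load_partner_labels(state, params, "coloc")
    both = (lab.data > 0) & (partner.data > 0)
    pairs, counts = (
        np.unique(
            np.stack([lab.data[both], partner.data[both]]), axis=1, return_counts=True
        )
        if both.any()
        else (np.zeros((2, 0), dtype=int), np.zeros(0, dtype=int))
    )
    size_a = np.bincount(lab.data.ravel(), minlength=lab.n_labels + 1)
    order = np.lexsort((pairs[1], pairs[0]))
    table = pd.DataFrame(
        {
            "labelA": pairs[0][order],
            "labelB": pairs[1][order],
            "overlap_voxels": counts[order],
            "overlap_fraction_of_A": counts[order] / size_a[pairs[0][order]],
        }
    )
    _write_analysis_table(state, table, params, "coloc")
    return state.current


@module(
    "numbering",
    ANA,
    "Count partner objects whose centroid voxel falls inside each current object",
    params=(
        ("dirRaw", None, "directory of the saved partner label map"),
        ("fileRaw", None, "file name of the saved partner label map"),
        ("dir", None, "target directory"),
        ("file", None, "CSV file name"),
    ),
)
def op_numbering(state, params):
    lab = _require_label(state, "numbering")
    partner = _load_partner_labels(state, params, "numbering")
    _, centroids = _centroids(partner)
    counts = np.zeros(lab.n_labels + 1, dtype=np.int64)
    shape = np.array(lab.shape)
    for c in centroids:
        voxel = np.clip(np.rint(c).astype(int), 0, shape - 1)
        counts[lab.data[tuple(voxel)]] += 1
    ids = lab.labels()
    table = pd.DataFrame({"label": ids, "count": counts[ids]})
    _write_analysis_table(state, table, params, "numbering")
    return state.current


@module(
    "distances",
    ANA,
    "Nearest partner object per current object, by calibrated centroid distance",
    params=(
        ("dirRaw", None, "directory of the saved partner label map"),
        ("fileRaw", None, "file name of the saved partner label map"),
        ("dir", None, "target directory"),
        ("file", None, "CSV file name"),
        ("mode", "nearest", "distance mode (nearest centroid)"),
    ),
)
def op_distances(state, params):
    if params["mode"].strip().casefold() != "nearest":
        raise ModuleError(f"distances: unknown mode {params['mode']!r}")
    lab = _require_label(state, "distances")
    partner = _load_partner_labels(state, params, "distances")
    ids_a, cen_a = _centroids(lab)
    ids_b, cen_b = _centroids(partner)
    cal = lab.calibration
    scale = np.array([cal.pixel_size_z, cal.pixel_size_xy, cal.pixel_size_xy])
    if len(ids_b) == 0:
        state.warn("distances: partner label map is empty")
        table = pd.DataFrame({"label": ids_a, "nearest": [], "distance": []})
    else:
        diff = cen_a[:, None, :] * scale - cen_b[None, :, :] * scale
        dist = np.sqrt((diff**2).sum(axis=2))
        nearest = np.argmin(dist, axis=1) if len(ids_a) else np.zeros(0, dtype=int)
        table = pd.DataFrame(
            {
                "label": ids_a,
                "nearest": ids_b[nearest] if len(ids_a) else [],
                "distance": dist[np.arange(len(ids_a)), nearest] if len(ids_a) else [],
            }
        )
    _write_analysis_table(state, table, params, "distances")
    return state.current


# --------------------------------------------------------------------------
# Measurements processing
# --------------------------------------------------------------------------


@module(
    "mergeTables",
    TAB,
    "Row-wise concatenation of CSV tables with an added 'source' column",
    params=(
        ("dir", None, "directory of the input tables"),
        ("list", None, "comma-separated CSV file names"),
        ("file", None, "output CSV file name"),
    ),
    needs_image=False,
)
def op_mergeTables(state, params):
    base = Path(params["dir"])
    frames = []
    for name in _split_list(params["list"]):
        path = base / name
        frame = read_table(path)
        frame.insert(0, "source", name)
        frames.append(frame)
    if not frames:
        raise ModuleError("mergeTables: empty table list")
    merged = pd.concat(frames, ignore_index=True, sort=False)
    write_table(merged, base / params["file"])
    return state.current


@module(
    "appendTables",
    TAB,
    "Column-wise join of CSV tables on their 'label' column",
    params=(
        ("dir", None, "directory of the input tables"),
        ("list", None, "comma-separated CSV file names"),
        ("file", None, "output CSV file name"),
    ),
    needs_image=False,
)
def op_appendTables(state, params):
    base = Path(params["dir"])
    joined = None
    for name in _split_list(params["list"]):
        frame = read_table(base / name)
        if "label" not in frame.columns:
            raise ModuleError(f"appendTables: {name!r} has no 'label' column")
        joined = frame if joined is None else joined.merge(frame, on="label", how="inner")
    if joined is None:
        raise ModuleError("appendTables: empty table list")
    write_table(joined, base / params["file"])
    return state.current
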